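"""Maximum-entropy ensemble reweighting with a Gaussian error model.

Frame weights are minimally perturbed (in relative-entropy sense) from the
prior so that reweighted ensemble averages match experimental observables
within their uncertainties.  With restraint matrix s (frames x K), targets
s_exp and uncertainties sigma, the posterior weights are

    w_i  propto  w0_i exp(-sum_k lambda_k s_ki)

with the multipliers minimizing the convex dual objective

    Gamma(lambda) = ln sum_i w0_i exp(-lambda . s_i)
                    + lambda . s_exp + 1/2 sum_k sigma_k^2 lambda_k^2.

At the optimum the stationarity identity <s_k>_w = s_exp,k + sigma_k^2
lambda_k holds; its residual is reported as a convergence diagnostic.  The
Kish ratio 100 / (N sum_i w_i^2) measures the effective fraction of frames
retained after reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .thermo_stats import blocking


@dataclass
class RestraintSet:
    observables: np.ndarray          # (frames, K) predicted per-frame values
    targets: np.ndarray              # (K,) experimental values
    sigma: np.ndarray | float        # (K,) or scalar uncertainty
    prior_weights: np.ndarray | None = None

    def __post_init__(self):
        self.observables = np.atleast_2d(np.asarray(self.observables, float))
        self.targets = np.atleast_1d(np.asarray(self.targets, float))
        n, k = self.observables.shape
        if self.targets.shape != (k,):
            raise ValueError("targets must have one entry per restraint")
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (k,)).copy()
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be positive")
        if self.prior_weights is None:
            self.prior_weights = np.full(n, 1.0 / n)
        else:
            w0 = np.asarray(self.prior_weights, dtype=float)
            if w0.shape != (n,) or np.any(w0 < 0):
                raise ValueError("prior weights must be nonnegative, one per frame")
            self.prior_weights = w0 / w0.sum()
        if not np.all(np.isfinite(self.observables)):
            raise ValueError("observable matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.observables.shape[0]

    @property
    def n_restraints(self) -> int:
        return self.observables.shape[1]


@dataclass
class ReweightResult:
    weights: np.ndarray              # posterior frame weights, sum to 1
    lambdas: np.ndarray              # Lagrange multipliers, one per restraint
    kish_percent: float
    reweighted_averages: np.ndarray
    stationarity_residual: np.ndarray   # <s>_w - s_exp - sigma^2 lambda
    objective: float
    n_iterations: int = 0
    extras: dict = field(default_factory=dict)


def kish_ratio(weights: np.ndarray) -> float:
    """Effective percentage of frames retained: 100 / (N sum w^2) for
    normalized weights (100 for uniform, 100/N for a single frame)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    w = w / w.sum()
    return 100.0 * w.sum() ** 2 / (w.size * np.sum(w**2))


def _weights_from_lambdas(restraints: RestraintSet,
                          lam: np.ndarray) -> np.ndarray:
    log_w = np.log(restraints.prior_weights + 1e-300) \
        - restraints.observables @ lam
    log_w -= logsumexp(log_w)
    return np.exp(log_w)


def _objective(lam, restraints: RestraintSet):
    s, w0 = restraints.observables, restraints.prior_weights
    logz = logsumexp(np.log(w0 + 1e-300) - s @ lam)
    gamma = logz + lam @ restraints.targets \
        + 0.5 * np.sum(restraints.sigma**2 * lam**2)
    w = np.exp(np.log(w0 + 1e-300) - s @ lam - logz)
    grad = -(s.T @ w) + restraints.targets + restraints.sigma**2 * lam
    return gamma, grad


def reweight(restraints: RestraintSet, lambda0: np.ndarray | None = None,
             gtol: float = 1e-10, max_iterations: int = 10_000) -> ReweightResult:
    """Solve the Gaussian-error maximum-entropy reweighting problem.

    The dual objective is smooth and convex, so a deterministic quasi-Newton
    minimization with the analytic gradient starting from lambda = 0 (or a
    supplied starting point, which must yield the same optimum) suffices.
    """
    if restraints.n_frames < 2:
        raise ValueError("need at least two frames to reweight")
    if restraints.n_restraints == 0:
        w = restraints.prior_weights.copy()
        return ReweightResult(weights=w, lambdas=np.zeros(0),
                              kish_percent=kish_ratio(w),
                              reweighted_averages=np.zeros(0),
                              stationarity_residual=np.zeros(0),
                              objective=0.0)
    lam0 = np.zeros(restraints.n_restraints) if lambda0 is None \
        else np.asarray(lambda0, dtype=float)
    res = minimize(_objective, lam0, args=(restraints,), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iterations, "gtol": gtol,
                            "ftol": 1e-15})
    grad_norm = float(np.linalg.norm(res.jac))
    if not res.success and grad_norm > 1e-6:
        raise RuntimeError(
            f"maximum-entropy reweighting did not converge after "
            f"{res.nit} iterations (gradient norm {grad_norm:.3e})")
    lam = res.x
    w = _weights_from_lambdas(restraints, lam)
    averages = restraints.observables.T @ w
    residual = averages - restraints.targets - restraints.sigma**2 * lam
    return ReweightResult(weights=w, lambdas=lam,
                          kish_percent=kish_ratio(w),
                          reweighted_averages=averages,
                          stationarity_residual=residual,
                          objective=float(res.fun), n_iterations=int(res.nit))


def reweighted_observable(series, weights: np.ndarray):
    """Weighted ensemble average of a per-frame series, with a blocking SE
    on the weighted series; returns a BlockingResult."""
    from .thermo_stats import _series_values

    x = _series_values(series)
    w = np.asarray(weights, dtype=float)
    if len(x) != len(w):
        raise ValueError("series and weights must be aligned")
    return blocking(x, weights=w)
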