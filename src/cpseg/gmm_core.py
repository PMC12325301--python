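"""EM for one-dimensional Gaussian mixtures and hard CP assignment.

The model is a K-component univariate mixture
``p(x) = sum_k pi_k N(x; mu_k, sigma_k^2)`` fitted by plain
expectation-maximization from a single fixed initialization (no random
restarts), so every run is reproducible without a seed. For choroid plexus
segmentation K = 3: a dark fluid component, an intermediate partial-volume
component and a bright plexus component, with published starting values
mu = [0.15, 1.5, 4], sigma = [0.02, 0.1, 1.5], pi = [0.45, 0.5, 0.05] on
mean-normalized intensities.

Responsibilities are computed in the log domain; component variances are
clamped at a small floor rather than letting a component collapse onto a
single sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)

#: Smallest admissible component standard deviation (normalized units).
VARIANCE_FLOOR = 1e-4
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(eq=False)
class MixtureParams:
    """Means, standard deviations and weights of a K-component 1-D mixture."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        k = self.means.size
        if self.sds.size != k or self.weights.size != k:
            raise ValueError("means, sds and weights must have equal length")
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be positive")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def k(self) -> int:
        return self.means.size


@dataclass(eq=False)
class FitResult:
    """EM bookkeeping: final parameters plus the log-likelihood trace."""

    params: MixtureParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    floor_engaged: bool = field(default=False)


def default_init() -> MixtureParams:
    """The published 3-component starting point for normalized FLAIR values.

    Dark fluid near 0.15, partial-volume shell near 1.5, bright plexus near
    4 (all relative to the region's non-zero mean intensity of 1).
    """
    return MixtureParams(means=[0.15, 1.5, 4.0],
                         sds=[0.02, 0.1, 1.5],
                         weights=[0.45, 0.5, 0.05])


def _as_values(samples) -> np.ndarray:
    values = getattr(samples, "values", samples)
    return np.asarray(values, dtype=np.float64).ravel()


def _log_joint(x: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log N(x_i; mu_k, sigma_k^2)."""
    z = (x[:, None] - params.means[None, :]) / params.sds[None, :]
    log_pdf = -0.5 * z * z - np.log(params.sds)[None, :] - _LOG_SQRT_2PI
    with np.errstate(divide="ignore"):  # zero weights are legal
        log_w = np.log(params.weights)
    return log_w[None, :] + log_pdf


def log_likelihood(samples, params: MixtureParams) -> float:
    """Total log-likelihood of the samples under the mixture."""
    x = _as_values(samples)
    return float(logsumexp(_log_joint(x, params), axis=1).sum())


def responsibilities(samples, params: MixtureParams) -> np.ndarray:
    """Posterior component probabilities, one row per sample (rows sum to 1)."""
    x = _as_values(samples)
    lj = _log_joint(x, params)
    return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))


def em_fit(samples, init: MixtureParams | None = None, tol: float = DEFAULT_TOL,
           max_iter: int = DEFAULT_MAX_ITER,
           variance_floor: float = VARIANCE_FLOOR) -> FitResult:
    """Fit the mixture by EM from a fixed initialization.

    Iterates standard E/M updates until the relative log-likelihood change
    drops below ``tol`` or ``max_iter`` is reached. Deterministic given
    (samples, init): there is no random restart and no dependence on sample
    order. A component whose standard deviation would fall below
    ``variance_floor`` is clamped to the floor (logged, not an error).

    Raises
    ------
    ValueError
        Fewer samples than mixture components, or a non-positive tolerance.
    """
    if init is None:
        init = default_init()
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = _as_values(samples)
    n, k = x.size, init.k
    if n < k:
        raise ValueError(f"need at least {k} samples to fit {k} components, got {n}")

    params = MixtureParams(init.means.copy(), init.sds.copy(), init.weights.copy())
    trace: list[float] = []
    converged = False
    floor_engaged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        lj = _log_joint(x, params)
        log_norm = logsumexp(lj, axis=1, keepdims=True)
        trace.append(float(log_norm.sum()))
        resp = np.exp(lj - log_norm)

        nk = resp.sum(axis=0)
        nk_safe = np.maximum(nk, np.finfo(float).tiny)
        means = (resp * x[:, None]).sum(axis=0) / nk_safe
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk_safe
        sds = np.sqrt(var)
        if np.any(sds < variance_floor):
            floor_engaged = True
            log.info("variance floor engaged for components %s",
                     np.flatnonzero(sds < variance_floor).tolist())
            sds = np.maximum(sds, variance_floor)
        params = MixtureParams(means=means, sds=sds, weights=nk / n)

        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            converged = True
            break

    trace.append(log_likelihood(x, params))
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=n_iter, converged=converged,
                     floor_engaged=floor_engaged)


def cp_component(params: MixtureParams) -> int:
    """Index of the component playing the CP role: the highest *fitted* mean.

    Component identity can swap during EM, so the role is read off the
    converged means, not the initial ones. Exact ties in the mean are broken
    toward the larger weight, then toward the higher index; the choice is
    deterministic.
    """
    top = np.flatnonzero(params.means == params.means.max())
    if top.size == 1:
        return int(top[0])
    heaviest = top[params.weights[top] == params.weights[top].max()]
    return int(heaviest[-1])


def assign_cp(samples, params: MixtureParams) -> np.ndarray:
    """Hard clustering: True where the highest-mean component wins the posterior.

    Posterior ties are broken toward the CP (higher-mean) component.
    An empty sample vector yields an empty assignment.
    """
    x = _as_values(samples)
    if x.size == 0:
        return np.zeros(0, dtype=bool)
    resp = responsibilities(x, params)
    cp = cp_component(params)
    return resp[:, cp] >= resp.max(axis=1)
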