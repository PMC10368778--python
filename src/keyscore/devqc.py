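"""Device and data-quality computations.

* a two-component Gaussian-mixture fit of key→sound latency samples, by
  expectation-maximisation, with the fraction of events meeting the ≤25 ms
  perceptual-latency requirement;
* the motion-exclusion rule: a participant is excluded when 10 or more
  volumes exceed a framewise displacement of one voxel dimension (2.5 mm);
* the skewness/kurtosis robustness bounds (2.31 and 8) under which the
  repeated-measures ANOVA F statistic tolerates non-normality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "LatencyFit",
    "MotionVerdict",
    "RobustnessResult",
    "fit_latency_mixture",
    "fraction_within_bound",
    "motion_exclusion",
    "robustness_check",
    "within_robustness_bounds",
    "DEFAULT_LATENCY_BOUND_MS",
    "SKEWNESS_BOUND",
    "KURTOSIS_BOUND",
]

DEFAULT_LATENCY_BOUND_MS = 25.0
SKEWNESS_BOUND = 2.31
KURTOSIS_BOUND = 8.0  # raw (Pearson) kurtosis; normal distribution = 3

_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class LatencyFit:
    """Gaussian-mixture parameters (components in ascending mean order)."""

    means_ms: tuple[float, ...]
    sds_ms: tuple[float, ...]
    weights: tuple[float, ...]
    fraction_within_bound: float
    bound_ms: float
    log_likelihood: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class MotionVerdict:
    """Outcome of the framewise-displacement exclusion rule."""

    n_volumes: int
    n_exceeding: int
    threshold_mm: float
    max_volumes: int
    excluded: bool


@dataclass(frozen=True)
class RobustnessResult:
    """Sample shape statistics and the ANOVA-robustness verdict.

    ``kurtosis`` is the raw (Pearson) form compared against the bound of 8;
    the excess form (raw − 3) is reported alongside.
    """

    skewness: float
    kurtosis: float
    kurtosis_excess: float
    within_bounds: bool


def _em_run(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    n = x.size
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space
        log_comp = (
            np.log(weights)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        # EM guarantees monotone likelihood; a violation beyond rounding
        # indicates an implementation bug, so fail loudly
        assert ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), (
            f"EM log-likelihood decreased: {ll_prev} -> {ll}"
        )
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        means = (resp @ x) / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        sds = np.sqrt(np.maximum(var, _VAR_FLOOR))
        weights = nk / n
        if ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return means, sds, weights, ll_prev, converged, it


def fit_latency_mixture(
    samples: Sequence[float],
    k: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int | None = 0,
    n_restarts: int = 5,
    bound_ms: float = DEFAULT_LATENCY_BOUND_MS,
) -> LatencyFit:
    """Maximum-likelihood Gaussian-mixture fit by EM with random restarts.

    Initial means are drawn around sample quantiles; the best-likelihood run
    is kept and components are reported in ascending mean order.  When no
    restart converges within ``max_iter`` iterations the best-so-far
    parameters are returned with ``converged=False``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} samples to fit {k} components")
    rng = np.random.default_rng(seed)
    sd0 = float(x.std()) or 1.0

    best: tuple | None = None
    base_means = np.quantile(x, (np.arange(k) + 0.5) / k)
    for r in range(n_restarts):
        means = base_means + (rng.normal(0, 0.25 * sd0, size=k) if r else 0.0)
        sds = np.full(k, max(sd0 / k, math.sqrt(_VAR_FLOOR)))
        weights = np.full(k, 1.0 / k)
        fit = _em_run(x, means, sds, weights, max_iter, tol)
        if best is None or fit[3] > best[3]:
            best = fit
    means, sds, weights, ll, converged, n_iter = best  # type: ignore[misc]
    order = np.argsort(means)
    return LatencyFit(
        means_ms=tuple(float(m) for m in means[order]),
        sds_ms=tuple(float(s) for s in sds[order]),
        weights=tuple(float(w) for w in weights[order]),
        fraction_within_bound=fraction_within_bound(x, bound_ms),
        bound_ms=bound_ms,
        log_likelihood=float(ll),
        converged=bool(converged),
        n_iter=int(n_iter),
    )


def fraction_within_bound(
    samples: Sequence[float], bound_ms: float = DEFAULT_LATENCY_BOUND_MS
) -> float:
    """Fraction of latency samples meeting the requirement (≤ bound, inclusive)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute a fraction of zero samples")
    return float(np.mean(x <= bound_ms))


def motion_exclusion(
    fd_series: Sequence[float],
    threshold_mm: float = 2.5,
    max_volumes: int = 10,
) -> MotionVerdict:
    """Apply the excessive-motion rule to a framewise-displacement series.

    A volume counts when FD strictly exceeds ``threshold_mm`` (one voxel
    dimension); the participant is excluded when ``max_volumes`` (default 10)
    or more volumes count.
    """
    fd = np.asarray(fd_series, dtype=float)
    if np.any(fd < 0):
        raise ValueError("framewise displacement cannot be negative")
    n_exceeding = int(np.sum(fd > threshold_mm))
    return MotionVerdict(
        n_volumes=int(fd.size),
        n_exceeding=n_exceeding,
        threshold_mm=threshold_mm,
        max_volumes=max_volumes,
        excluded=n_exceeding >= max_volumes,
    )


def within_robustness_bounds(
    skewness: float,
    kurtosis: float,
    skew_bound: float = SKEWNESS_BOUND,
    kurtosis_bound: float = KURTOSIS_BOUND,
) -> bool:
    """Whether shape statistics fall inside the ANOVA-robustness region
    (|skewness| ≤ 2.31 and kurtosis ≤ 8)."""
    return abs(skewness) <= skew_bound and kurtosis <= kurtosis_bound


def robustness_check(
    values: Sequence[float],
    skew_bound: float = SKEWNESS_BOUND,
    kurtosis_bound: float = KURTOSIS_BOUND,
) -> RobustnessResult:
    """Sample skewness and kurtosis with the robustness verdict.

    Uses bias-corrected sample estimators; the bound of 8 applies to raw
    (Pearson) kurtosis, and the excess form is reported for reference.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for skewness and kurtosis")
    skew = float(sps.skew(x, bias=False))
    kurt_raw = float(sps.kurtosis(x, fisher=False, bias=False))
    return RobustnessResult(
        skewness=skew,
        kurtosis=kurt_raw,
        kurtosis_excess=kurt_raw - 3.0,
        within_bounds=within_robustness_bounds(
            skew, kurt_raw, skew_bound, kurtosis_bound
        ),
    )
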