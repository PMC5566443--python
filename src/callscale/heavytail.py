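"""Heavy-tail model fitting for inter-event intervals.

Implements maximum-likelihood power-law fitting with Kolmogorov–Smirnov
lower-bound selection, a semiparametric bootstrap goodness-of-fit p-value,
and the exponential and lognormal competitors.

Conventions
-----------
All empirical/model comparisons use the *complementary* CDF (survival
function): the power-law tail model is

    P(T >= tau) = (tau / tau_min) ** (1 - alpha),      tau >= tau_min > 0,

which equals 1 at the lower bound and falls as a straight line on log-log
axes.  A power law with exponent ``alpha`` has a finite mean only for
``alpha > 2`` and a finite variance only for ``alpha > 3``; the intervals of
dyadic calling typically sit in the finite-mean, infinite-variance regime
``2 < alpha < 3``.

Three exponent estimators are exposed:

``continuous``  (default)
    Hill-type MLE for real-valued intervals,
    ``alpha = 1 + n / sum(ln(tau_i / tau_min))``.
``paper-eq4``
    The discrete-data approximation with the -1/2 continuity correction,
    ``alpha = 1 + n / sum(ln(tau_i / (tau_min - 1/2)))``; requires
    ``tau_min > 1/2``.
``discrete``
    Exact discrete (zeta) likelihood, maximized numerically with the Hurwitz
    zeta function; intended for integer-valued data.

The lower bound ``tau_min`` is chosen by scanning candidate bounds (by
default every distinct positive observed value except the largest) and
keeping the candidate whose fitted tail minimizes the KS distance between
the renormalized empirical tail CCDF and the model CCDF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import optimize, special, stats

from .interaction import IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "EstimatorMode",
    "PowerLawFit",
    "ExponentialFit",
    "LognormalFit",
    "ModelComparison",
    "powerlaw_ccdf",
    "estimate_alpha",
    "ks_distance",
    "fit_powerlaw",
    "gof_pvalue",
    "fit_exponential",
    "fit_lognormal",
    "compare_models",
]

EstimatorMode = Literal["continuous", "paper-eq4", "discrete"]

#: tail sizes below which the exponent estimate is flagged
RELIABLE_TAIL = 50
GOOD_TAIL = 100


@dataclass
class PowerLawFit:
    """A fitted power-law tail: exponent, lower bound and fit quality."""

    alpha: float
    tau_min: float
    ks_distance: float
    n_tail: int
    estimator_mode: EstimatorMode = "continuous"
    gof_pvalue: float | None = None
    warnings: tuple[str, ...] = ()

    def ccdf(self, tau):
        return powerlaw_ccdf(tau, self.alpha, self.tau_min)


@dataclass
class ExponentialFit:
    """Exponential model P(T >= tau) = exp(-tau/mu); MLE mu = sample mean."""

    mu: float
    ks_distance: float
    ks_pvalue: float


@dataclass
class LognormalFit:
    """Lognormal model fitted by log-moment MLE on the positive intervals."""

    mu_log: float
    sigma_log: float
    ks_distance: float
    ks_pvalue: float
    n_excluded_zeros: int = 0


@dataclass
class ModelComparison:
    """Pass/fail verdicts for the three candidate models at one level."""

    powerlaw: PowerLawFit
    exponential: ExponentialFit
    lognormal: LognormalFit
    level: float = 0.01
    n_tests: int = 3

    @property
    def verdicts(self) -> dict[str, bool]:
        return {
            "power-law": self.powerlaw.gof_pvalue is not None
            and self.powerlaw.gof_pvalue > self.level,
            "exponential": self.exponential.ks_pvalue > self.level,
            "lognormal": self.lognormal.ks_pvalue > self.level,
        }

    @property
    def preferred(self) -> str:
        pvals = {
            "power-law": self.powerlaw.gof_pvalue,
            "exponential": self.exponential.ks_pvalue,
            "lognormal": self.lognormal.ks_pvalue,
        }
        passers = {m: p for m, p in pvals.items() if self.verdicts[m] and p is not None}
        if not passers:
            return "none"
        return max(passers, key=passers.get)


def _as_array(intervals) -> np.ndarray:
    if isinstance(intervals, IntervalSet):
        return intervals.taus
    return np.asarray(intervals, dtype=float)


def powerlaw_ccdf(tau, alpha: float, tau_min: float):
    """P(T >= tau) = (tau/tau_min)**(1-alpha) for tau >= tau_min."""
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1, got {alpha}")
    if tau_min <= 0:
        raise ValueError(f"tau_min must be positive, got {tau_min}")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < tau_min):
        raise ValueError("tau below the lower bound tau_min")
    out = (tau_arr / tau_min) ** (1.0 - alpha)
    return float(out) if np.isscalar(tau) else out


def _discrete_alpha_mle(taus: np.ndarray, tau_min: float) -> float:
    """Maximize the Hurwitz-zeta likelihood of a discrete power law."""
    n = taus.size
    sum_log = np.log(taus).sum()

    def neg_loglik(alpha: float) -> float:
        return alpha * sum_log + n * np.log(special.zeta(alpha, tau_min))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(1.0 + 1e-6, 30.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def estimate_alpha(
    taus,
    tau_min: float,
    estimator_mode: EstimatorMode = "continuous",
) -> float:
    """Maximum-likelihood exponent of the tail (all intervals >= tau_min)."""
    taus = _as_array(taus)
    if taus.size == 0:
        raise ValueError("no intervals in the tail")
    if np.any(taus < tau_min):
        raise ValueError("all intervals must be >= tau_min")
    if estimator_mode == "continuous":
        if tau_min <= 0:
            raise ValueError("continuous estimator needs tau_min > 0")
        denom = np.log(taus / tau_min).sum()
    elif estimator_mode == "paper-eq4":
        if tau_min <= 0.5:
            raise ValueError("the -1/2-corrected estimator needs tau_min > 1/2")
        denom = np.log(taus / (tau_min - 0.5)).sum()
    elif estimator_mode == "discrete":
        if tau_min < 1:
            raise ValueError("discrete estimator needs integer-scale tau_min >= 1")
        return _discrete_alpha_mle(taus, tau_min)
    else:
        raise ValueError(f"unknown estimator_mode {estimator_mode!r}")
    if denom <= 0:
        raise ValueError("degenerate tail: all intervals at the lower bound")
    return 1.0 + taus.size / denom


def _ks_tail(sorted_tail: np.ndarray, model_ccdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """KS distance between the renormalized empirical tail CCDF and a model.

    Evaluated at the distinct observed points with both one-sided step
    limits, so the supremum over the step function is attained exactly.
    """
    m = sorted_tail.size
    if m == 0:
        raise ValueError("empty tail")
    vals, counts = np.unique(sorted_tail, return_counts=True)
    cum = np.cumsum(counts)  # number of points <= vals[j]
    emp_hi = 1.0 - (cum - counts) / m  # empirical CCDF just below/at vals[j]
    emp_lo = 1.0 - cum / m  # just above vals[j]
    model = model_ccdf(vals)
    return float(
        np.maximum(np.abs(emp_hi - model), np.abs(emp_lo - model)).max()
    )


def ks_distance(taus, ccdf_model: Callable[[np.ndarray], np.ndarray], tau_min: float) -> float:
    """Supremum distance between empirical tail CCDF and a model CCDF.

    The empirical CCDF is restricted to ``tau >= tau_min`` and renormalized
    to the tail; ``ccdf_model`` must satisfy ``ccdf_model(tau_min) = 1``.
    """
    taus = _as_array(taus)
    tail = np.sort(taus[taus >= tau_min])
    if tail.size == 0:
        raise ValueError("no intervals at or above tau_min")
    return _ks_tail(tail, ccdf_model)


def _scan_discrete(
    sorted_taus: np.ndarray, candidates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate zeta-likelihood fit (numeric MLE, so no vectorization)."""
    n = sorted_taus.size
    alphas = np.empty(candidates.size)
    dists = np.empty(candidates.size)
    n_tails = np.empty(candidates.size, dtype=int)
    for k, x in enumerate(candidates):
        i = np.searchsorted(sorted_taus, x, side="left")
        n_tails[k] = n - i
        alpha = _discrete_alpha_mle(sorted_taus[i:], x)
        alphas[k] = alpha
        z_min = special.zeta(alpha, x)
        dists[k] = _ks_tail(
            sorted_taus[i:], lambda v, a=alpha, z=z_min: special.zeta(a, v) / z
        )
    return alphas, dists, n_tails


#: candidate-block size for the vectorized scan (memory ~ block * n_unique)
_SCAN_BLOCK = 128


def _scan(
    sorted_taus: np.ndarray,
    candidates: np.ndarray,
    estimator_mode: EstimatorMode,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitted alpha and KS distance for every candidate lower bound.

    ``sorted_taus`` must be sorted ascending and strictly positive.  The
    continuous/corrected estimators are scanned in blocks of candidates with
    broadcast KS evaluation; results match the one-candidate-at-a-time
    computation exactly.  Returns (alphas, distances, n_tails).
    """
    if estimator_mode == "discrete":
        return _scan_discrete(sorted_taus, candidates)

    n = sorted_taus.size
    vals, counts = np.unique(sorted_taus, return_counts=True)
    cum = np.cumsum(counts)
    n_ge = n - cum + counts  # points >= vals[j]  (empirical CCDF numerators)
    n_gt = n - cum  # points >  vals[j]
    log_vals = np.log(vals)
    # suffix sums of log tau at each distinct value for O(1) MLE denominators
    suffix_log = np.concatenate([np.cumsum((counts * log_vals)[::-1])[::-1], [0.0]])

    first = np.searchsorted(vals, candidates, side="left")  # candidate -> unique index
    m_tail = n_ge[np.minimum(first, vals.size - 1)].astype(float)
    m_tail[first >= vals.size] = 0.0
    ref = candidates - 0.5 if estimator_mode == "paper-eq4" else candidates
    denom = suffix_log[first] - m_tail * np.log(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        alphas = np.where(denom > 0, 1.0 + m_tail / denom, np.inf)

    dists = np.full(candidates.size, np.inf)
    col = np.arange(vals.size)
    for a in range(0, candidates.size, _SCAN_BLOCK):
        b = min(a + _SCAN_BLOCK, candidates.size)
        ok = np.isfinite(alphas[a:b])
        if not ok.any():
            continue
        with np.errstate(invalid="ignore", over="ignore"):
            expo = (1.0 - alphas[a:b, None]) * (
                log_vals[None, :] - np.log(candidates[a:b, None])
            )
            model = np.exp(expo)
        inv_m = 1.0 / m_tail[a:b, None]
        diff = np.maximum(
            np.abs(n_ge[None, :] * inv_m - model),
            np.abs(n_gt[None, :] * inv_m - model),
        )
        diff[col[None, :] < first[a:b, None]] = -np.inf  # values below the bound
        block = diff.max(axis=1)
        block[~ok] = np.inf
        dists[a:b] = block
    return alphas, dists, n_tails_from(first, n_ge)


def n_tails_from(first: np.ndarray, n_ge: np.ndarray) -> np.ndarray:
    safe = np.minimum(first, n_ge.size - 1)
    out = n_ge[safe].copy()
    out[first >= n_ge.size] = 0
    return out.astype(int)


def fit_powerlaw(
    intervals,
    estimator_mode: EstimatorMode = "continuous",
    tau_min_grid: np.ndarray | None = None,
    max_candidates: int | None = None,
) -> PowerLawFit:
    """Fit a power-law tail with KS-minimizing lower-bound selection.

    Every candidate lower bound (default: each distinct positive observed
    interval except the largest) is tried; the tail above it is fitted by
    maximum likelihood and scored by the KS distance between the
    renormalized empirical tail CCDF and the fitted model CCDF.  The
    candidate minimizing the distance wins (first minimum on ties, i.e. the
    smallest such bound).

    Parameters
    ----------
    intervals
        :class:`IntervalSet` or array of intervals; zeros are excluded
        (logarithms undefined below any positive bound).
    estimator_mode
        ``continuous`` (default), ``paper-eq4`` or ``discrete``.
    tau_min_grid
        Explicit candidate bounds; overrides the default grid.
    max_candidates
        Optional coarsening: subsample the default grid to at most this many
        evenly spaced candidates (always keeping the smallest).
    """
    taus = _as_array(intervals)
    pos = np.sort(taus[taus > 0])
    if pos.size < 2:
        raise ValueError("need at least 2 positive intervals")
    if pos[0] == pos[-1]:
        raise ValueError("degenerate distribution: all intervals identical")
    if tau_min_grid is not None:
        candidates = np.sort(np.asarray(tau_min_grid, dtype=float))
        if candidates.size == 0:
            raise ValueError("empty tau_min grid")
    else:
        distinct = np.unique(pos)
        candidates = distinct[:-1]  # excluding the largest: a 1-point tail is unfittable
        if estimator_mode == "paper-eq4":
            candidates = candidates[candidates > 0.5]
            if candidates.size == 0:
                raise ValueError("no candidate tau_min > 1/2 for the corrected estimator")
        if max_candidates is not None and candidates.size > max_candidates:
            idx = np.unique(
                np.linspace(0, candidates.size - 1, max_candidates).round().astype(int)
            )
            candidates = candidates[idx]

    alphas, dists, n_tails = _scan(pos, candidates, estimator_mode)
    if not np.any(np.isfinite(dists)):
        raise ValueError("no candidate lower bound admits a fit")
    best = int(np.argmin(dists))

    notes = []
    if n_tails[best] < RELIABLE_TAIL:
        notes.append(
            f"unreliable: only {n_tails[best]} tail events (< {RELIABLE_TAIL})"
        )
        logger.warning("fit_powerlaw: %s", notes[-1])
    elif n_tails[best] < GOOD_TAIL:
        notes.append(
            f"limited precision: {n_tails[best]} tail events (< {GOOD_TAIL})"
        )
        logger.info("fit_powerlaw: %s", notes[-1])
    return PowerLawFit(
        alpha=float(alphas[best]),
        tau_min=float(candidates[best]),
        ks_distance=float(dists[best]),
        n_tail=int(n_tails[best]),
        estimator_mode=estimator_mode,
        warnings=tuple(notes),
    )


def _sample_tail(rng: np.random.Generator, n: int, alpha: float, tau_min: float) -> np.ndarray:
    u = rng.random(n)
    return tau_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def gof_pvalue(
    fit: PowerLawFit,
    intervals,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    max_candidates: int | None = None,
) -> float:
    """Semiparametric bootstrap goodness-of-fit p-value for a power-law fit.

    Each replicate draws ``n`` points: with probability ``n_tail/n`` from the
    fitted power law above ``tau_min``, otherwise resampled uniformly from
    the observed values below ``tau_min``.  The replicate is refitted by the
    full lower-bound scan and its KS distance recorded; the p-value is the
    fraction of replicates whose distance is at least the observed one.  A
    p-value near 1 means the model reproduces data like the observed ones; a
    small p-value means the observed distance is atypical under the model.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    taus = _as_array(intervals)
    pos = taus[taus > 0]
    n = pos.size
    below = pos[pos < fit.tau_min]
    p_tail = fit.n_tail / n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(n) < p_tail
        m = int(take_tail.sum())
        rep = np.empty(n)
        rep[:m] = _sample_tail(rng, m, fit.alpha, fit.tau_min)
        if n - m:
            if below.size == 0:  # whole sample is tail; resample tail only
                rep[m:] = _sample_tail(rng, n - m, fit.alpha, fit.tau_min)
            else:
                rep[m:] = rng.choice(below, size=n - m, replace=True)
        try:
            rep_fit = fit_powerlaw(
                rep, estimator_mode=fit.estimator_mode, max_candidates=max_candidates
            )
        except ValueError:  # pathological replicate (e.g. all identical)
            exceed += 1
            continue
        if rep_fit.ks_distance >= fit.ks_distance:
            exceed += 1
    return exceed / n_boot


def fit_exponential(intervals) -> ExponentialFit:
    """Exponential MLE (mu = sample mean) with a one-sample KS test.

    All intervals, including zeros, enter the fit; the KS p-value is the
    asymptotic one-sample p and is approximate because mu is estimated from
    the same data.
    """
    taus = _as_array(intervals)
    if taus.size < 2:
        raise ValueError("need at least 2 intervals")
    if np.any(taus < 0):
        raise ValueError("intervals must be non-negative")
    mu = float(taus.mean())
    if mu <= 0:
        raise ValueError("degenerate sample: mean interval is zero")
    res = stats.kstest(taus, "expon", args=(0, mu))
    return ExponentialFit(mu=mu, ks_distance=float(res.statistic), ks_pvalue=float(res.pvalue))


def fit_lognormal(intervals) -> LognormalFit:
    """Lognormal MLE (log-moment closed form) on the positive intervals.

    ``mu_log`` is the mean of ln tau and ``sigma_log`` the 1/n (maximum
    likelihood) standard deviation of ln tau.  Zeros cannot carry lognormal
    mass; they are excluded and counted.
    """
    taus = _as_array(intervals)
    n_zeros = int((taus <= 0).sum())
    pos = taus[taus > 0]
    if pos.size < 2:
        raise ValueError("need at least 2 positive intervals")
    logs = np.log(pos)
    mu_log = float(logs.mean())
    sigma_log = float(logs.std(ddof=0))
    if sigma_log <= 0:
        raise ValueError("degenerate sample: zero log-scale variance")
    res = stats.kstest(pos, "lognorm", args=(sigma_log, 0, np.exp(mu_log)))
    return LognormalFit(
        mu_log=mu_log,
        sigma_log=sigma_log,
        ks_distance=float(res.statistic),
        ks_pvalue=float(res.pvalue),
        n_excluded_zeros=n_zeros,
    )


def compare_models(
    intervals,
    level: float = 0.01,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    estimator_mode: EstimatorMode = "continuous",
    max_candidates: int | None = None,
) -> ModelComparison:
    """Fit all three models and declare pass/fail verdicts at ``level``.

    The power law passes when its bootstrap goodness-of-fit p-value exceeds
    the level; the competitors when their one-sample KS p-values do.  The
    preferred model is the passer with the highest p-value, or ``"none"``.
    """
    pl = fit_powerlaw(intervals, estimator_mode=estimator_mode, max_candidates=max_candidates)
    pl.gof_pvalue = gof_pvalue(
        pl, intervals, n_boot=n_boot, seed=seed, max_candidates=max_candidates
    )
    expo = fit_exponential(intervals)
    logn = fit_lognormal(intervals)
    return ModelComparison(powerlaw=pl, exponential=expo, lognormal=logn, level=level)
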