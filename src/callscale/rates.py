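"""Call-rate dynamics: binned rates, rate changes, spectra, circadian control.

Call activity is summarized per individual as a binned rate series: within
each observation window, bins of width ``bin_width`` (default 30 s) count the
calls, the call rate is ``gamma = counts / width`` (calls/s) and the rate
change ``delta_gamma`` is the first difference of gamma *within* a contiguous
window (never across a gap such as night).  Linearity of the cumulative count
curve and of the rate series is summarized by OLS R-squared, and the spectrum
of delta_gamma by a plain one-sided periodogram whose log-log OLS slope is
~0 for white noise and positive when successive rate changes alternate fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .events_io import ActivityMask
from .interaction import ClassifiedCall

__all__ = [
    "RateSeries",
    "Periodogram",
    "CircadianBiasReport",
    "call_rate_series",
    "rate_periodogram",
    "circadian_bias",
]


@dataclass
class RateSeries:
    """Binned call counts and rates for one individual, gap-aware."""

    bin_width: float
    bin_starts: np.ndarray  # seconds, start of each bin
    bin_widths: np.ndarray  # actual width (final bin of a window may be partial)
    counts: np.ndarray  # calls per bin
    segment_ids: np.ndarray  # which contiguous window each bin belongs to
    r2_cumulative: float
    r2_rate: float

    @property
    def gamma(self) -> np.ndarray:
        """Call rate per bin, calls/s."""
        return self.counts / self.bin_widths

    @property
    def delta_gamma_segments(self) -> list[np.ndarray]:
        """First differences of gamma within each contiguous window."""
        g = self.gamma
        return [
            np.diff(g[self.segment_ids == s])
            for s in np.unique(self.segment_ids)
            if (self.segment_ids == s).sum() >= 2
        ]

    @property
    def delta_gamma(self) -> np.ndarray:
        segs = self.delta_gamma_segments
        return np.concatenate(segs) if segs else np.empty(0)


@dataclass
class Periodogram:
    """One-sided power spectrum of the rate-change series."""

    freqs: np.ndarray  # cycles per bin step, zero excluded
    power: np.ndarray
    slope: float  # OLS slope of log10 power vs log10 freq


class CircadianBiasReport(NamedTuple):
    """Association between an event's preceding interval and its clock time."""

    rho: float  # Spearman rank correlation
    pvalue: float  # permutation p-value
    n: int
    n_permutations: int


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.allclose(y, y[0]):
        return 1.0  # a constant is fitted exactly by its own flat line
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def call_rate_series(
    event_times: np.ndarray,
    mask: ActivityMask,
    bin_width: float = 30.0,
) -> RateSeries:
    """Bin one individual's calls over the mask windows into a rate series.

    Bins tile each window from its start; a final partial bin keeps its true
    width so counts are conserved.  R-squared of the cumulative count is the
    OLS fit of N(t) against t at bin right edges; R-squared of the rate is
    the OLS fit of gamma against bin midpoints.
    """
    times = np.sort(np.asarray(event_times, dtype=float))
    if times.size < 3:
        raise ValueError("need at least 3 events for a rate series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if all(end - start < bin_width for start, end in mask.windows):
        raise ValueError("bin_width exceeds every mask window")

    starts, widths, counts, seg_ids = [], [], [], []
    for seg, (w_start, w_end) in enumerate(mask.windows):
        edges = np.arange(w_start, w_end, bin_width)
        rights = np.minimum(edges + bin_width, w_end)
        in_bin = np.histogram(times, bins=np.append(edges, w_end))[0]
        starts.append(edges)
        widths.append(rights - edges)
        counts.append(in_bin)
        seg_ids.append(np.full(edges.size, seg))
    bin_starts = np.concatenate(starts)
    bin_widths = np.concatenate(widths)
    bin_counts = np.concatenate(counts).astype(float)
    segment_ids = np.concatenate(seg_ids)

    cumulative = np.cumsum(bin_counts)
    right_edges = bin_starts + bin_widths
    r2_cum = _ols_r2(right_edges, cumulative)
    midpoints = bin_starts + bin_widths / 2
    r2_rate = _ols_r2(midpoints, bin_counts / bin_widths)

    return RateSeries(
        bin_width=float(bin_width),
        bin_starts=bin_starts,
        bin_widths=bin_widths,
        counts=bin_counts,
        segment_ids=segment_ids,
        r2_cumulative=r2_cum,
        r2_rate=r2_rate,
    )


def _one_sided_periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram normalized so that total power equals the series variance."""
    n = x.size
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2 / n**2
    freqs = np.fft.rfftfreq(n)  # cycles per step
    spec = spec[1:]
    freqs = freqs[1:]
    # double interior frequencies (conjugate pairs); Nyquist (even n) stays single
    weights = np.full(spec.size, 2.0)
    if n % 2 == 0:
        weights[-1] = 1.0
    return freqs, spec * weights


def rate_periodogram(series: RateSeries | Sequence[float], min_points: int = 16) -> Periodogram:
    """One-sided periodogram of the mean-removed rate-change series.

    When the rate series spans several contiguous windows, each window's
    delta-gamma segment gets its own periodogram and the spectra are
    averaged on a common frequency grid (segments cropped to the shortest
    usable length).  The slope is the OLS fit of log10 power against log10
    frequency over all nonzero frequencies.
    """
    if isinstance(series, RateSeries):
        segments = [s for s in series.delta_gamma_segments if s.size >= min_points]
    else:
        arr = np.asarray(series, dtype=float)
        segments = [arr] if arr.size >= min_points else []
    if not segments:
        raise ValueError(f"need a contiguous rate-change segment of >= {min_points} points")
    if all(np.allclose(s, s[0]) for s in segments):
        raise ValueError("degenerate series: rate changes are constant")

    n_common = min(s.size for s in segments)
    spectra = []
    for seg in segments:
        freqs, power = _one_sided_periodogram(seg[:n_common])
        spectra.append(power)
    power = np.mean(spectra, axis=0)

    keep = power > 0  # exact spectral zeros carry no log-log information
    if keep.sum() < 2:
        raise ValueError("degenerate series: too few nonzero spectral estimates")
    res = stats.linregress(np.log10(freqs[keep]), np.log10(power[keep]))
    return Periodogram(freqs=freqs, power=power, slope=float(res.slope))


def circadian_bias(
    classified: Sequence[ClassifiedCall],
    mask: ActivityMask | None = None,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> CircadianBiasReport:
    """Test whether long-interval calls cluster at particular times of day.

    If power-law-like interval statistics were an artifact of a daily
    activity cycle, events following long intervals would concentrate at
    specific clock times.  This reports the Spearman rank correlation
    between each classified event's preceding interval tau and its clock
    time, with a permutation p-value (tau values shuffled against times); it
    is a descriptive report, not a thresholded verdict.
    """
    pairs = [(c.tau, c.event.time) for c in classified if c.tau is not None]
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 classified events, got {len(pairs)}")
    taus = np.array([p[0] for p in pairs])
    times = np.array([p[1] for p in pairs])
    rho = float(stats.spearmanr(taus, times).statistic)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_rho = stats.spearmanr(rng.permutation(taus), times).statistic
        if abs(perm_rho) >= abs(rho):
            exceed += 1
    pvalue = (exceed + 1) / (n_permutations + 1)
    return CircadianBiasReport(rho=rho, pvalue=pvalue, n=len(pairs), n_permutations=n_permutations)
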