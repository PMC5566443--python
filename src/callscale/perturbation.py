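"""Paired comparison of power-law exponents across experimental conditions.

A perturbation (partner separation, isolation, water removal) is assessed by
pairing each dyad's fitted exponent under condition A with its exponent
under condition B and testing the per-pair differences ``alpha_A - alpha_B``
with the Wilcoxon signed-rank test.  Sidedness is gated: the one-sided test
in the expected direction is run and reported only when the two-sided test
is significant at the chosen level (default 5%).

* expected *decrease* (e.g. cohabitation minus separation for the reactive
  modes): one-sided alternative "median difference greater than 0";
* expected *increase* (e.g. baseline minus water-removal for the male
  self-contained mode): alternative "median difference less than 0".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PairedExponents",
    "WilcoxonResult",
    "pair_exponents",
    "compare_exponents",
    "perturbation_report",
]


@dataclass
class PairedExponents:
    """Per-pair exponents for one mode under two conditions."""

    mode: str
    condition_a: str
    condition_b: str
    pairs: list[tuple[str, float, float]]  # (pair id, alpha_a, alpha_b)

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicated pair ids in {ids}")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def differences(self) -> np.ndarray:
        return np.array([a - b for _, a, b in self.pairs], dtype=float)


@dataclass
class WilcoxonResult:
    """Sidedness-gated signed-rank outcome for one paired contrast."""

    statistic: float
    p_two_sided: float
    p_one_sided: float | None  # only when the two-sided test was significant
    side: str  # "greater", "less" or "none"
    significant: bool
    direction_of_change: str  # sign of the median difference: "decrease"/"increase"/"none"
    n: int
    level: float = 0.05


def pair_exponents(
    fits: Mapping[tuple[str, str, str], float] | pd.DataFrame,
    condition_a: str,
    condition_b: str,
    mode: str,
) -> PairedExponents:
    """Inner-join per-pair exponents of two conditions for one mode.

    ``fits`` is either a mapping ``(pair, condition, mode) -> alpha`` or a
    DataFrame with columns ``pair, condition, mode, alpha``.  Pairs missing
    either condition are dropped with a logged count.
    """
    if isinstance(fits, pd.DataFrame):
        sub = fits[fits["mode"] == mode]
        table = {(r.pair, r.condition): float(r.alpha) for r in sub.itertuples()}
    else:
        table = {(p, c): float(a) for (p, c, m), a in fits.items() if m == mode}
    pairs_a = {p for p, c in table if c == condition_a}
    pairs_b = {p for p, c in table if c == condition_b}
    common = sorted(pairs_a & pairs_b)
    n_dropped = len(pairs_a | pairs_b) - len(common)
    if n_dropped:
        logger.info(
            "pair_exponents(%s, %s vs %s): dropped %d pairs missing a condition",
            mode, condition_a, condition_b, n_dropped,
        )
    if not common:
        raise ValueError(
            f"no pairs have fits in both {condition_a!r} and {condition_b!r} for mode {mode!r}"
        )
    return PairedExponents(
        mode=mode,
        condition_a=condition_a,
        condition_b=condition_b,
        pairs=[(p, table[(p, condition_a)], table[(p, condition_b)]) for p in common],
    )


def compare_exponents(
    paired: PairedExponents,
    expected_direction: str = "two_sided",
    level: float = 0.05,
) -> WilcoxonResult:
    """Signed-rank test of the per-pair exponent differences, sidedness-gated.

    ``expected_direction``: ``decrease`` means alpha is expected to drop from
    A to B (differences > 0, one-sided alternative "greater"); ``increase``
    the opposite; ``two_sided`` skips the gated one-sided step.  Zero
    differences are dropped before ranking; the exact null distribution is
    used for small n without ties, the normal approximation otherwise.
    """
    if expected_direction not in ("decrease", "increase", "two_sided"):
        raise ValueError(f"unknown expected_direction {expected_direction!r}")
    d = paired.differences
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if d.size < 5:
        logger.warning(
            "compare_exponents: n=%d is below the exact-distribution regime "
            "the test is normally reported at; interpret with care", d.size,
        )
    median_d = float(np.median(d))
    if np.all(d == 0):
        return WilcoxonResult(
            statistic=0.0, p_two_sided=1.0, p_one_sided=None, side="none",
            significant=False, direction_of_change="none", n=int(d.size), level=level,
        )
    two = stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox")
    p_two = float(two.pvalue)
    significant = p_two < level
    p_one = None
    side = "none"
    if significant and expected_direction != "two_sided":
        side = "greater" if expected_direction == "decrease" else "less"
        one = stats.wilcoxon(d, alternative=side, zero_method="wilcox")
        p_one = float(one.pvalue)
    direction = "none"
    if median_d > 0:
        direction = "decrease"  # alpha_a > alpha_b: the exponent dropped from A to B
    elif median_d < 0:
        direction = "increase"
    return WilcoxonResult(
        statistic=float(two.statistic),
        p_two_sided=p_two,
        p_one_sided=p_one,
        side=side,
        significant=significant,
        direction_of_change=direction,
        n=int(d.size),
        level=level,
    )


def perturbation_report(
    comparisons: Iterable[tuple[PairedExponents, WilcoxonResult]],
) -> pd.DataFrame:
    """One row per (mode, contrast): n, median difference, p-values, verdict.

    No multiplicity correction is applied (each contrast is reported at its
    own level); the number of tests is implicit in the row count.
    """
    rows = []
    for paired, result in comparisons:
        rows.append(
            {
                "mode": paired.mode,
                "condition_a": paired.condition_a,
                "condition_b": paired.condition_b,
                "n": result.n,
                "median_delta_alpha": float(np.median(paired.differences)),
                "p_two_sided": result.p_two_sided,
                "p_one_sided": result.p_one_sided,
                "side": result.side,
                "significant": result.significant,
                "direction_of_change": result.direction_of_change,
            }
        )
    if not rows:
        raise ValueError("no comparisons to report")
    return pd.DataFrame(rows)
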