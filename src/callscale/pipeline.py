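"""Orchestration: per-pair and whole-study analysis runs.

``run_pair`` takes one dyad recording through classification, the four
mode-wise interval analyses and model comparisons, both birds' rate and
spectral summaries and the circadian-bias control, and returns a
JSON-serializable report.  ``run_study`` maps ``run_pair`` over a collection
of recordings and assembles the paired exponent contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .events_io import DyadRecording
from .heavytail import EstimatorMode, compare_models
from .interaction import MODES, classify_calls, interval_summary, intervals_by_mode
from .perturbation import compare_exponents, pair_exponents, perturbation_report
from .rates import call_rate_series, circadian_bias, rate_periodogram

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PairReport", "run_pair", "run_study"]

#: modes whose exponent is expected to react to each canonical contrast,
#: with the expected direction of change from condition A to condition B
DEFAULT_DIRECTIONS = {"decrease": "decrease", "increase": "increase"}


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one analysis run; recorded verbatim in every report."""

    bin_width: float = 30.0
    estimator_mode: EstimatorMode = "continuous"
    n_boot: int = 200
    gof_level: float = 0.01
    wilcoxon_level: float = 0.05
    min_intervals: int = 10
    max_candidates: int | None = None
    label_filter: str | None = None
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PairReport:
    """Full per-recording analysis: intervals, fits, rates, provenance."""

    pair_id: str
    condition: str
    n_events: int
    modes: dict[str, dict[str, Any]]
    rates: dict[str, dict[str, Any]]
    circadian: dict[str, Any] | None
    config: dict[str, Any]
    seed: int
    version: str = __version__
    incomplete_stages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    def exponents(self) -> dict[str, float]:
        """Fitted power-law exponent per mode (only modes that were fit)."""
        return {
            m: info["powerlaw"]["alpha"]
            for m, info in self.modes.items()
            if "powerlaw" in info
        }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pair(recording: DyadRecording, config: RunConfig = RunConfig()) -> PairReport:
    """Analyze one recording end to end.

    Per mode: interval summary and three-model comparison (skipped with a
    marker when fewer than ``config.min_intervals`` intervals survive).  Per
    bird: rate series and periodogram.  Plus the circadian-bias report.
    Stages that cannot run are flagged in ``incomplete_stages``, never
    silently dropped.
    """
    rng = np.random.default_rng(config.seed)
    incomplete: list[str] = []
    classified = classify_calls(recording)

    modes_out: dict[str, dict[str, Any]] = {}
    for mode in MODES:
        intervals = intervals_by_mode(
            classified, mode, mask=recording.mask,
            pair_id=recording.pair_id, condition=recording.condition,
        )
        if config.label_filter is not None:
            keep = [
                c.tau for c in classified
                if c.mode == mode and c.event.label == config.label_filter
            ]
            intervals.taus = np.array(keep, dtype=float)
        info: dict[str, Any] = {"n": intervals.n}
        if intervals.n >= 1:
            summ = interval_summary(intervals)
            info["summary"] = summ._asdict()
        if intervals.n < config.min_intervals:
            info["status"] = "insufficient data"
            incomplete.append(f"fit:{mode}")
        else:
            try:
                comparison = compare_models(
                    intervals,
                    level=config.gof_level,
                    n_boot=config.n_boot,
                    seed=rng,
                    estimator_mode=config.estimator_mode,
                    max_candidates=config.max_candidates,
                )
            except ValueError as exc:
                info["status"] = f"fit failed: {exc}"
                incomplete.append(f"fit:{mode}")
            else:
                info["status"] = "ok"
                info["powerlaw"] = dataclasses.asdict(comparison.powerlaw)
                info["exponential"] = dataclasses.asdict(comparison.exponential)
                info["lognormal"] = dataclasses.asdict(comparison.lognormal)
                info["verdicts"] = comparison.verdicts
                info["preferred"] = comparison.preferred
        modes_out[mode] = info

    rates_out: dict[str, dict[str, Any]] = {}
    for ind in recording.individuals:
        role = recording.role_of(ind)
        try:
            series = call_rate_series(
                recording.times_of(ind), recording.mask, bin_width=config.bin_width
            )
            entry: dict[str, Any] = {
                "individual": ind,
                "n_bins": int(series.counts.size),
                "mean_gamma": float(series.gamma.mean()),
                "r2_cumulative": series.r2_cumulative,
                "r2_rate": series.r2_rate,
            }
            try:
                pgram = rate_periodogram(series)
                entry["periodogram_slope"] = pgram.slope
            except ValueError as exc:
                entry["periodogram_slope"] = None
                incomplete.append(f"periodogram:{role}")
        except ValueError as exc:
            entry = {"individual": ind, "status": f"rates failed: {exc}"}
            incomplete.append(f"rates:{role}")
        rates_out[role] = entry

    try:
        circ = circadian_bias(classified, recording.mask, seed=rng)._asdict()
    except ValueError:
        circ = None
        incomplete.append("circadian")

    return PairReport(
        pair_id=recording.pair_id,
        condition=recording.condition,
        n_events=recording.n_events,
        modes=modes_out,
        rates=rates_out,
        circadian=circ,
        config=config.to_dict(),
        seed=config.seed,
        incomplete_stages=incomplete,
    )


def run_study(
    recordings: Iterable[DyadRecording],
    contrasts: Sequence[tuple[str, str, str]] = (),
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Analyze a collection of recordings and run the condition contrasts.

    ``contrasts`` lists ``(condition_a, condition_b, expected_direction)``
    triples; each is tested for all four modes.  Returns a dict with the
    per-pair reports, a flat exponent table and the perturbation report;
    optionally writes JSON + CSV under ``out_dir``.
    """
    reports = [run_pair(rec, config) for rec in recordings]
    if not reports:
        raise ValueError("no recordings to analyze")
    rows = []
    for rep in reports:
        for mode, alpha in rep.exponents().items():
            rows.append(
                {"pair": rep.pair_id, "condition": rep.condition, "mode": mode, "alpha": alpha}
            )
    exponents = pd.DataFrame(rows, columns=["pair", "condition", "mode", "alpha"])

    available = set(exponents["condition"]) if len(exponents) else set()
    comparisons = []
    for cond_a, cond_b, direction in contrasts:
        for missing in {cond_a, cond_b} - available:
            raise ValueError(f"contrast references absent condition {missing!r}")
        for mode in MODES:
            try:
                paired = pair_exponents(exponents, cond_a, cond_b, mode)
            except ValueError:
                logger.warning("no paired fits for %s %s vs %s", mode, cond_a, cond_b)
                continue
            result = compare_exponents(paired, direction, level=config.wilcoxon_level)
            comparisons.append((paired, result))
    report_df = perturbation_report(comparisons) if comparisons else None

    study = {
        "config": config.to_dict(),
        "n_recordings": len(reports),
        "pair_reports": [r.to_dict() for r in reports],
        "exponents": exponents,
        "perturbation": report_df,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = dict(study, exponents=exponents.to_dict("records"))
        if report_df is not None:
            serializable["perturbation"] = report_df.to_dict("records")
        (out / "study.json").write_text(
            json.dumps(serializable, indent=2, default=_jsonable)
        )
        exponents.to_csv(out / "exponents.csv", index=False)
        if report_df is not None:
            report_df.to_csv(out / "perturbation.csv", index=False)
    return study
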