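"""Percent-error tables, error reductions, and inter-observer statistics.

All comparisons use the signed percent-error convention

    error = 100 * (measured - baseline) / baseline

against either the gold standard (the known dispensed activity) or the
reference vial placed away from the metal (measured-vs-measured).  Error
reduction between two attenuation-correction strategies is the drop in
error magnitude, |error_a| - |error_b|, in percentage points.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import VialMeasurement

GOLD = "gold_standard"
REFERENCE = "reference_vial"
TOTAL_ACTIVITY = "total_activity"
CONCENTRATION = "activity_concentration"


def percent_error(measured: float, baseline: float) -> float:
    """Signed percent error of ``measured`` relative to ``baseline``."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero for a percent error")
    return 100.0 * (measured - baseline) / baseline


@dataclass(frozen=True)
class ErrorRecord:
    target: str  # vial name or "total"
    comparison: str  # gold_standard | reference_vial
    quantity: str  # total_activity | activity_concentration
    percent_error: float


class ErrorTable:
    """Per-strategy lists of :class:`ErrorRecord`, one per (target, quantity, comparison)."""

    def __init__(self, records: Mapping[str, Sequence[ErrorRecord]] | None = None):
        self.records: dict[str, list[ErrorRecord]] = {
            k: list(v) for k, v in (records or {}).items()
        }

    @property
    def strategies(self) -> list[str]:
        return list(self.records)

    def add(self, strategy: str, record: ErrorRecord) -> None:
        existing = self.records.setdefault(strategy, [])
        for r in existing:
            if (r.target, r.quantity, r.comparison) == (
                record.target, record.quantity, record.comparison,
            ):
                raise ValueError(
                    f"duplicate record for {strategy}/{record.target}/"
                    f"{record.quantity}/{record.comparison}"
                )
        existing.append(record)

    def get(
        self,
        strategy: str,
        target: str,
        quantity: str = TOTAL_ACTIVITY,
        comparison: str = GOLD,
    ) -> float:
        for r in self.records.get(strategy, []):
            if (r.target, r.quantity, r.comparison) == (target, quantity, comparison):
                return r.percent_error
        raise KeyError(
            f"no record for strategy={strategy!r} target={target!r} "
            f"quantity={quantity!r} comparison={comparison!r}"
        )

    def select(self, strategy: str) -> "ErrorTable":
        if strategy not in self.records:
            raise KeyError(f"no strategy {strategy!r} in table")
        return ErrorTable({strategy: self.records[strategy]})

    @property
    def only_strategy(self) -> str:
        if len(self.records) != 1:
            raise ValueError("table holds multiple strategies; select one")
        return next(iter(self.records))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": s,
                "target": r.target,
                "comparison": r.comparison,
                "quantity": r.quantity,
                "percent_error": r.percent_error,
            }
            for s, recs in self.records.items()
            for r in recs
        ]
        return pd.DataFrame(rows)


def build_error_table(
    measurements: Mapping[str, Sequence[VialMeasurement]],
    ground_truth,
    whole_volume_totals: Mapping[str, float] | None = None,
) -> ErrorTable:
    """Errors vs gold standard (all vials + optional whole-volume total) and
    vs the reference vial (anterior/mid/posterior, measured-vs-measured).

    Per-vial comparisons use RC-corrected means/totals; the whole-volume
    total is raw (no RC is defined for an unsegmented volume).
    """
    table = ErrorTable()
    for strategy, ms in measurements.items():
        by_name = {m.name: m for m in ms}
        if "reference" not in by_name:
            raise ValueError(f"strategy {strategy!r}: reference vial missing")
        ref = by_name["reference"]
        for m in ms:
            truth = ground_truth.vial(m.name)
            table.add(strategy, ErrorRecord(
                m.name, GOLD, TOTAL_ACTIVITY,
                percent_error(m.total_rc_mbq, truth.activity_mbq)))
            table.add(strategy, ErrorRecord(
                m.name, GOLD, CONCENTRATION,
                percent_error(m.mean_rc_mbq_per_ml, truth.concentration_mbq_per_ml)))
            if m.name != "reference":
                table.add(strategy, ErrorRecord(
                    m.name, REFERENCE, TOTAL_ACTIVITY,
                    percent_error(m.total_rc_mbq, ref.total_rc_mbq)))
                table.add(strategy, ErrorRecord(
                    m.name, REFERENCE, CONCENTRATION,
                    percent_error(m.mean_rc_mbq_per_ml, ref.mean_rc_mbq_per_ml)))
        if whole_volume_totals is not None and strategy in whole_volume_totals:
            table.add(strategy, ErrorRecord(
                "total", GOLD, TOTAL_ACTIVITY,
                percent_error(whole_volume_totals[strategy],
                              ground_truth.total_activity_mbq)))
    return table


def error_reduction(
    errors_a: ErrorTable,
    errors_b: ErrorTable,
    target: str,
    quantity: str = CONCENTRATION,
    comparison: str = GOLD,
    strategy_a: str | None = None,
    strategy_b: str | None = None,
) -> float:
    """Drop in error magnitude from strategy a to strategy b, in percentage points."""
    a = errors_a.get(strategy_a or errors_a.only_strategy, target, quantity, comparison)
    b = errors_b.get(strategy_b or errors_b.only_strategy, target, quantity, comparison)
    return abs(a) - abs(b)


@dataclass
class InterObserverReport:
    """Signed per-target differences (observer1 - observer2) and their summary.

    ``mean_difference_magnitude`` is the magnitude of the mean signed
    difference (not the mean of magnitudes); ``max_abs_difference`` is the
    largest absolute per-target difference.
    """

    targets: list[str]
    differences: list[float]

    def __post_init__(self):
        if len(self.targets) != len(self.differences):
            raise ValueError("targets and differences must align")

    @property
    def mean_signed_difference(self) -> float:
        return float(np.mean(self.differences))

    @property
    def mean_difference_magnitude(self) -> float:
        return abs(self.mean_signed_difference)

    @property
    def max_abs_difference(self) -> float:
        return float(np.max(np.abs(self.differences)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"target": self.targets, "difference": self.differences})


def interobserver_stats(
    errors_obs1: Sequence[float],
    errors_obs2: Sequence[float],
    targets: Sequence[str] | None = None,
) -> InterObserverReport:
    """Per-target signed differences between two observers' percent errors."""
    if len(errors_obs1) != len(errors_obs2):
        raise ValueError(
            f"observer error lists differ in length: {len(errors_obs1)} vs {len(errors_obs2)}"
        )
    diffs = [float(a) - float(b) for a, b in zip(errors_obs1, errors_obs2)]
    if targets is None:
        targets = [f"target_{i}" for i in range(len(diffs))]
    return InterObserverReport(list(targets), diffs)
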