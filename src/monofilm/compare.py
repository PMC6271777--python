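"""Feature tables across lipids and subphases, and control-relative statistics.

The summary table mirrors the customary layout of monolayer interaction
studies: one block per lipid, one column per test substance (water first),
and fixed parameter rows (lift-off area, collapse pressure, maximal C_s⁻¹,
condensed-state surface potential, reported dipole area).  Comparisons are
always against the water control of the same lipid: a positive percent
change means the compound *lowered* the parameter ("reduction"), and fold
reductions are control ÷ treatment, defined only when both values are
positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import AggregationError, MissingControlError, UndefinedComparisonError
from .features import MonolayerFeatureSet
from .io import IsothermMetadata

CONTROL_SUBPHASE = "water"

#: Fixed parameter rows of the summary table, in display order.
PARAMETER_ROWS = (
    "liftoff_area",
    "collapse_pressure",
    "max_modulus",
    "max_potential",
    "reported_dipole_area",
)

PARAMETER_LABELS = {
    "liftoff_area": "lift-off value (A2/molecule)",
    "collapse_pressure": "collapse pressure (mN/m)",
    "max_modulus": "max compressibility modulus Cs-1 (mN/m)",
    "max_potential": "surface potential (mV)",
    "reported_dipole_area": "surface dipole moment area (A2/molecule)",
}


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fold_reduction(
    control: float, treatment: float, rounding: str = "none"
) -> float:
    """control ÷ treatment; 'how many times smaller the treatment is'.

    Both values must be positive — a ratio across a sign change is
    meaningless.  ``rounding='nearest_integer'`` rounds ties away from
    zero, matching the headline "n-fold" phrasing.
    """
    if control <= 0 or treatment <= 0:
        raise UndefinedComparisonError(
            f"fold reduction undefined for control={control}, treatment={treatment}"
        )
    ratio = control / treatment
    if rounding == "nearest_integer":
        return float(_round_half_away(ratio))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return ratio


def percent_reduction(
    control: float, treatment: float, rounding: str = "none"
) -> float:
    """100·(control − treatment)/|control|; positive = reduction."""
    if control == 0:
        raise UndefinedComparisonError("percent reduction undefined for zero control")
    pct = 100.0 * (control - treatment) / abs(control)
    if rounding == "nearest_integer":
        return float(_round_half_away(pct))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return pct


@dataclass
class FeatureTable:
    """Rows keyed by (lipid, subphase) → MonolayerFeatureSet."""

    rows: dict[tuple[str, str], MonolayerFeatureSet] = field(default_factory=dict)

    def lipids(self) -> list[str]:
        seen: list[str] = []
        for lipid, _ in self.rows:
            if lipid not in seen:
                seen.append(lipid)
        return seen

    def subphases(self, lipid: str) -> list[str]:
        subs = [s for (l, s) in self.rows if l == lipid]
        # water control first, then stable order of appearance
        return sorted(subs, key=lambda s: (s != CONTROL_SUBPHASE, subs.index(s)))

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: parameter rows × (lipid, substance) columns."""
        cols = {}
        for lipid in self.lipids():
            for sub in self.subphases(lipid):
                fs = self.rows[(lipid, sub)]
                cols[(lipid, sub)] = {
                    PARAMETER_LABELS[p]: getattr(fs, p) for p in PARAMETER_ROWS
                }
        df = pd.DataFrame(cols)
        df = df.reindex([PARAMETER_LABELS[p] for p in PARAMETER_ROWS])
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["lipid", "subphase"])
        return df

    def to_csv(self) -> str:
        return self.to_frame().to_csv(float_format="%.6g")

    def to_markdown(self) -> str:
        """Markdown rendering, one block per lipid."""
        lines: list[str] = []
        for lipid in self.lipids():
            subs = self.subphases(lipid)
            lines.append(f"### {lipid}")
            lines.append("| Parameter | " + " | ".join(subs) + " |")
            lines.append("|---" * (len(subs) + 1) + "|")
            for p in PARAMETER_ROWS:
                cells = []
                for s in subs:
                    v = getattr(self.rows[(lipid, s)], p)
                    cells.append("" if v is None else f"{v:.4g}")
                lines.append(
                    f"| {PARAMETER_LABELS[p]} | " + " | ".join(cells) + " |"
                )
            lines.append("")
        return "\n".join(lines)


def build_feature_table(
    feature_sets: Iterable[tuple[IsothermMetadata, MonolayerFeatureSet]]
) -> FeatureTable:
    """Assemble per-curve feature sets into one summary table.

    Each feature set must carry lipid and subphase metadata; duplicate
    (lipid, subphase) keys are an aggregation error.  A missing water
    control does not prevent table assembly — only later comparisons.
    """
    table = FeatureTable()
    for meta, fs in feature_sets:
        key = (meta.lipid, meta.subphase_additive)
        if not key[0]:
            raise AggregationError("feature set without lipid metadata")
        if key in table.rows:
            raise AggregationError(f"duplicate (lipid, subphase) key {key}")
        table.rows[key] = fs
    return table


@dataclass(frozen=True)
class ComparisonResult:
    """Control-vs-treatment statistics for one (lipid, compound, parameter).

    ``percent_change`` is positive for a reduction; ``fold_reduction`` is
    control ÷ treatment, None when undefined (sign change or zero
    treatment); ``direction`` labels increases explicitly.
    """

    lipid: str
    compound: str
    parameter: str
    control_value: float
    treatment_value: float
    delta: float
    percent_change: float
    fold_reduction: Optional[float]

    @property
    def direction(self) -> str:
        if self.percent_change > 0:
            return "reduction"
        if self.percent_change < 0:
            return "increase"
        return "unchanged"


def compare_to_control(table: FeatureTable, parameter: str) -> list[ComparisonResult]:
    """One result per (lipid, compound) against that lipid's water control.

    Results are ordered by (lipid, compound), so the output does not depend
    on the order in which rows were added.  Raises MissingControlError
    naming the first lipid without a water row.
    """
    if parameter not in PARAMETER_ROWS:
        raise ValueError(f"unknown parameter {parameter!r}; one of {PARAMETER_ROWS}")
    results: list[ComparisonResult] = []
    for lipid in sorted(table.lipids()):
        if (lipid, CONTROL_SUBPHASE) not in table.rows:
            raise MissingControlError(f"no water control for lipid {lipid!r}")
        control = getattr(table.rows[(lipid, CONTROL_SUBPHASE)], parameter)
        if control is None:
            continue
        for sub in sorted(s for (l, s) in table.rows if l == lipid):
            if sub == CONTROL_SUBPHASE:
                continue
            treatment = getattr(table.rows[(lipid, sub)], parameter)
            if treatment is None:
                continue
            fold: Optional[float]
            if control > 0 and treatment > 0:
                fold = control / treatment
            else:
                fold = None
            results.append(
                ComparisonResult(
                    lipid=lipid,
                    compound=sub,
                    parameter=parameter,
                    control_value=float(control),
                    treatment_value=float(treatment),
                    delta=float(control - treatment),
                    percent_change=percent_reduction(control, treatment),
                    fold_reduction=fold,
                )
            )
    return results


def summarize_folds(results: Iterable[ComparisonResult]) -> dict[str, dict[str, float]]:
    """Per-lipid min/max fold reduction over the compounds where defined."""
    summary: dict[str, dict[str, float]] = {}
    for r in results:
        if r.fold_reduction is None:
            continue
        entry = summary.setdefault(
            r.lipid, {"min_fold": float("inf"), "max_fold": -float("inf")}
        )
        entry["min_fold"] = min(entry["min_fold"], r.fold_reduction)
        entry["max_fold"] = max(entry["max_fold"], r.fold_reduction)
    return summary


def comparisons_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    recs = []
    for r in results:
        recs.append(
            {
                "lipid": r.lipid,
                "compound": r.compound,
                "parameter": r.parameter,
                "control_value": r.control_value,
                "treatment_value": r.treatment_value,
                "delta": r.delta,
                "percent_change": r.percent_change,
                "fold_reduction": r.fold_reduction,
                "direction": r.direction,
            }
        )
    return pd.DataFrame.from_records(recs)
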