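"""Multi-evidence integration: condition-specificity classes and the final
prioritized regulator report.

The two condition-specific consensus sets (stress at its threshold,
control at its lower threshold) are partitioned into stress-specific,
control-specific and shared regulators; an independent promoter-binding
evidence list (e.g. ChIP-seq derived) acts as a binary filter/flag.  The
final priority places binding-evidenced, stress-specific, high-frequency
regulators first — the tier where the study's top candidate sits.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "regulator",
    "class",
    "frequency_stress",
    "frequency_control",
    "mean_importance_stress",
    "binding_evidence",
    "priority",
)

_CLASS_ORDER = {"stress-specific": 0, "shared": 1, "control-specific": 2}


class ConditionClasses(NamedTuple):
    stress_only: list[str]
    control_only: list[str]
    shared: list[str]


def classify_condition_specific(
    stress_set: Sequence[str], control_set: Sequence[str]
) -> ConditionClasses:
    """Exact three-way partition of the union of the two retained sets,
    preserving input (rank) order within each class."""
    control = set(control_set)
    stress = set(stress_set)
    return ConditionClasses(
        stress_only=[g for g in stress_set if g not in control],
        control_only=[g for g in control_set if g not in stress],
        shared=[g for g in stress_set if g in control],
    )


def filter_by_binding(regulators: Sequence[str], binding_set: set[str]) -> list[str]:
    """Order-preserving intersection with the binding-evidence list."""
    binding = set(binding_set)
    return [g for g in regulators if g in binding]


def build_report(
    stress_table: pd.DataFrame,
    control_table: pd.DataFrame,
    thresholds: tuple[float, float] = (0.80, 0.40),
    binding_set: set[str] | None = None,
) -> pd.DataFrame:
    """Final prioritization from the two consensus tables.

    ``thresholds`` is (stress, control).  Regulators retained in either
    condition are classified, flagged with binding evidence and ordered by
    (binding desc, stress-specific first, stress frequency desc, mean
    stress importance desc, identifier asc); ``priority`` numbers that
    order from 1.
    """
    from .consensus import threshold_consensus

    t_stress, t_control = thresholds
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    binding = set(binding_set) if binding_set is not None else set()

    stress_set = threshold_consensus(stress_table, t_stress)
    control_set = threshold_consensus(control_table, t_control)
    classes = classify_condition_specific(stress_set, control_set)
    label = {g: "stress-specific" for g in classes.stress_only}
    label.update({g: "shared" for g in classes.shared})
    label.update({g: "control-specific" for g in classes.control_only})

    freq_s = dict(zip(stress_table["regulator"], stress_table["frequency"]))
    freq_c = dict(zip(control_table["regulator"], control_table["frequency"]))
    imp_s = dict(zip(stress_table["regulator"], stress_table["mean_importance"]))

    rows = [
        {
            "regulator": g,
            "class": label[g],
            "frequency_stress": float(freq_s.get(g, 0.0)),
            "frequency_control": float(freq_c.get(g, 0.0)),
            "mean_importance_stress": float(imp_s.get(g, 0.0)),
            "binding_evidence": g in binding,
        }
        for g in label
    ]
    report = pd.DataFrame(rows, columns=[c for c in REPORT_COLUMNS if c != "priority"])
    if not report.empty:
        report = report.sort_values(
            by=["binding_evidence", "class", "frequency_stress", "mean_importance_stress", "regulator"],
            ascending=[False, True, False, False, True],
            key=lambda col: col.map(_CLASS_ORDER) if col.name == "class" else col,
        ).reset_index(drop=True)
    report["priority"] = pd.Series(range(1, len(report) + 1), dtype=int)
    logger.info(
        "report: %d stress-specific, %d control-specific, %d shared, %d with binding evidence",
        len(classes.stress_only), len(classes.control_only), len(classes.shared),
        int(report["binding_evidence"].sum()) if not report.empty else 0,
    )
    return report
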