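"""Univariate decision rules for chemoreceptor ligands.

Two single-threshold classifiers summarize the study's findings: a compound
is called an attractant if its minimum electron potential q- lies strictly
below a threshold (default -280 kJ/mol; the Tsr-related rule), and an
aspartate analog is called an attractant if the distance R between its two
carboxyl carbons lies strictly below ~4 Å (the Tar-related rule). Boundary
values go to the other class. The companion structural rule predicts
attractant iff the carbon-chain length between the carboxyls, N_Carbon,
equals 2. Potency is expressed as cellular sensitivity = -log10(K_D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import (
    FunctionalGroupAttribution,
    LabeledTable,
    ValidationError,
    register_report_kind,
)
from .group_stats import GroupComparison, compare_groups

__all__ = [
    "ThresholdRule",
    "EqualityRule",
    "RuleReport",
    "classify",
    "scan_threshold",
    "sensitivity",
    "ncarbon_rule",
    "amine_effect",
    "functional_group_summary",
    "TH_Q_MINUS",
    "R_THRESHOLD",
]

TH_Q_MINUS = -280.0  # kJ/mol, q- threshold
R_THRESHOLD = 4.0    # Å, inter-carboxyl distance threshold


@register_report_kind
@dataclass(frozen=True)
class ThresholdRule:
    descriptor: str
    threshold: float
    direction: str  # below_is_attractant | above_is_attractant

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if self.direction not in ("below_is_attractant", "above_is_attractant"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def predict(self, value: float) -> int:
        """1 = attractant, 0 = non-attractant; strict inequality."""
        if self.direction == "below_is_attractant":
            return int(value < self.threshold)
        return int(value > self.threshold)


@register_report_kind
@dataclass(frozen=True)
class EqualityRule:
    """Predict attractant iff the (integer) descriptor equals ``value``."""

    descriptor: str
    value: int

    def predict(self, value: float) -> int:
        return int(value == self.value)


@register_report_kind
@dataclass
class RuleReport:
    rule: ThresholdRule | EqualityRule | None
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    misclassified: list[int]                       # serial_ids
    subgroup_accuracies: dict[str, tuple[int, int]]  # name -> (correct, total)
    excluded: list[int] = field(default_factory=list)
    tie_thresholds: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _default_subgroup(rec) -> str:
    return "n_carboxyl=2" if rec.n_carboxyl == 2 else "other"


def classify(
    rule: ThresholdRule | EqualityRule,
    table: LabeledTable,
    subgroup=_default_subgroup,
) -> RuleReport:
    """Apply a univariate rule; tally confusion, errors, subgroup accuracy.

    Compounds lacking the rule's descriptor are excluded with a warning and
    listed in the report. The default subgroup partition separates aspartate
    analogs (two carboxyl groups) from the rest.
    """
    if not table.records:
        raise ValidationError("cannot classify an empty table")
    y_true, y_pred, kept, excluded = [], [], [], []
    for rec in table.records:
        v = rec.value(rule.descriptor)
        if v is None:
            excluded.append(rec.serial_id)
            continue
        kept.append(rec)
        y_true.append(1 if rec.label == "attractant" else 0)
        y_pred.append(rule.predict(float(v)))
    if excluded:
        warnings.warn(
            f"{len(excluded)} compounds lack {rule.descriptor!r} and were "
            f"excluded: {excluded}",
            stacklevel=2,
        )
    if not kept:
        raise ValidationError(f"no compound carries {rule.descriptor!r}")

    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    mis = [r.serial_id for r, t, p in zip(kept, y_true, y_pred) if t != p]

    sub: dict[str, list[int]] = {}
    for rec, t, p in zip(kept, y_true, y_pred):
        key = subgroup(rec)
        c, n = sub.get(key, [0, 0])
        sub[key] = [c + int(t == p), n + 1]
    subgroups = {k: (v[0], v[1]) for k, v in sub.items()}

    return RuleReport(
        rule=rule, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(kept),
        misclassified=mis,
        subgroup_accuracies=subgroups,
        excluded=excluded,
    )


def scan_threshold(
    values: Sequence[float],
    labels: Sequence[int],
    direction: str = "below_is_attractant",
    descriptor: str = "q-",
) -> tuple[ThresholdRule, "ScanReport"]:
    """Find the accuracy-maximizing single threshold.

    Candidates are the midpoints between consecutive sorted distinct values
    plus one sentinel below the minimum and one above the maximum (the
    all-one-class rules), so the best training accuracy over every possible
    cut is attained. Ties are broken toward the smallest threshold and the
    full tie set is reported.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValidationError("both classes needed to scan a threshold")
    distinct = np.unique(values)
    cands = [float(distinct[0] - 1.0)]
    cands += [float((a + b) / 2) for a, b in zip(distinct[:-1], distinct[1:])]
    cands.append(float(distinct[-1] + 1.0))

    def acc(th: float) -> float:
        if direction == "below_is_attractant":
            pred = (values < th).astype(int)
        else:
            pred = (values > th).astype(int)
        return float(np.mean(pred == labels))

    accs = [acc(t) for t in cands]
    best = max(accs)
    ties = [t for t, a in zip(cands, accs) if a == best]
    rule = ThresholdRule(descriptor, min(ties), direction)

    if direction == "below_is_attractant":
        pred = (values < rule.threshold).astype(int)
    else:
        pred = (values > rule.threshold).astype(int)
    tp = int(np.sum((labels == 1) & (pred == 1)))
    fp = int(np.sum((labels == 0) & (pred == 1)))
    tn = int(np.sum((labels == 0) & (pred == 0)))
    fn = int(np.sum((labels == 1) & (pred == 0)))
    report = RuleReport(
        rule=rule, tp=tp, fp=fp, tn=tn, fn=fn, accuracy=best,
        misclassified=[int(i) for i in np.flatnonzero(pred != labels)],
        subgroup_accuracies={},
        tie_thresholds=ties,
    )
    return rule, report


ScanReport = RuleReport  # scan_threshold's report is an ordinary rule report


def sensitivity(k_d: float) -> float:
    """Cellular sensitivity -log10(K_D); monotone decreasing in K_D."""
    if not k_d > 0:
        raise ValidationError(f"k_d must be > 0, got {k_d!r}")
    return -math.log10(k_d)


def ncarbon_rule(table: LabeledTable) -> RuleReport:
    """Predict attractant iff N_Carbon (chain between carboxyls) equals 2."""
    for rec in table.records:
        if rec.n_carbon is None:
            raise ValidationError(
                f"compound {rec.serial_id} lacks n_carbon; the rule needs it"
            )
    return classify(EqualityRule("n_carbon", 2), table)


def amine_effect(table: LabeledTable) -> GroupComparison:
    """Sensitivity of attractants with an amino group vs without.

    Group 1 = attractants carrying >= 1 NH2 group, group 2 = attractants
    without; values are -log10(K_D). Requires K_D for every attractant.
    """
    vals, has_nh2 = [], []
    for rec in table.records:
        if rec.label != "attractant":
            continue
        if rec.k_d is None:
            raise ValidationError(
                f"attractant {rec.serial_id} lacks k_d; sensitivity undefined"
            )
        if rec.n_nh2 is None:
            raise ValidationError(f"attractant {rec.serial_id} lacks n_nh2")
        vals.append(sensitivity(rec.k_d))
        has_nh2.append(1 if rec.n_nh2 >= 1 else 0)
    if not vals:
        raise ValidationError("no attractants with k_d in table")
    return compare_groups(np.asarray(vals), np.asarray(has_nh2))


def functional_group_summary(
    attributions: Sequence[FunctionalGroupAttribution],
) -> dict[str, tuple[float, float | None, int]]:
    """Per-functional-group (mean, SD, n) of the attributed q-.

    Sample SD (divisor n-1); groups with a single member report SD as None.
    """
    if not attributions:
        raise ValidationError("no attributions supplied")
    groups: dict[str, list[float]] = {}
    for a in attributions:
        groups.setdefault(a.group, []).append(a.q_minus)
    out: dict[str, tuple[float, float | None, int]] = {}
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        out[g] = (float(arr.mean()), sd, len(arr))
    return out
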