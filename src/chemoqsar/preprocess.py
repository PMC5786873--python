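"""Descriptor normalization and rank-correlation redundancy filtering.

Before model construction every descriptor column is z-scored,
``z = (x - mu) / sigma`` (population sigma, divisor n, matching the default
of common ML toolkits; switchable via ``ddof``). Collinear descriptors are
then pruned on the Spearman rank-correlation matrix: any pair with
``|rho| > threshold`` (default 0.7, strict) is considered redundant.

Two pruning strategies are provided. ``explicit_list`` reproduces the
published seven-descriptor selection (E, E_sol, E_H-E_L, D, q-, q_ion-, q+):
the published removed/retained split is not derivable from the correlation
rule alone (e.g. A_CPK has no |rho| > 0.7 with any retained descriptor yet
was removed), so the published list is shipped as data. ``greedy_degree`` is
the general-purpose algorithm: iteratively delete the descriptor involved in
the most violating pairs until no pair exceeds the threshold.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core_data import (
    CorrelationMatrix,
    LabeledTable,
    RETAINED_DESCRIPTORS,
    ValidationError,
    register_report_kind,
)

__all__ = [
    "FilterResult",
    "zscore_normalize",
    "spearman_matrix",
    "redundancy_filter",
    "PAPER_RETAINED",
]

#: the published post-filter descriptor set
PAPER_RETAINED = RETAINED_DESCRIPTORS


@register_report_kind
@dataclass
class FilterResult:
    retained: list[str]
    removed: list[tuple[str, str, float]]  # (name, blocking partner, rho)
    threshold: float
    strategy: str

    @property
    def removed_names(self) -> list[str]:
        return [r[0] for r in self.removed]


def zscore_normalize(table: LabeledTable, ddof: int = 0) -> LabeledTable:
    """Return a copy of ``table`` with every descriptor column z-scored.

    Population convention (``ddof=0``) by default. Labels, potencies and
    structural annotations are untouched. A zero-variance column is an error
    naming the column.
    """
    out = copy.deepcopy(table)
    for name in table.descriptor_names:
        col = table.column(name)
        mu = col.mean()
        sd = col.std(ddof=ddof)
        if sd == 0:
            raise ValidationError(f"descriptor {name!r} has zero variance")
        z = (col - mu) / sd
        for rec, v in zip(out.records, z):
            rec.descriptors[name] = float(v)
    return out


def spearman_matrix(
    table: LabeledTable, names: tuple[str, ...] | None = None
) -> CorrelationMatrix:
    """Spearman rank correlation of descriptor columns (midranks for ties)."""
    names = tuple(names) if names is not None else table.descriptor_names
    if len(table) < 3:
        raise ValidationError("spearman_matrix requires at least 3 compounds")
    ranks = np.column_stack([rankdata(table.column(n)) for n in names])
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    # enforce exact symmetry / unit diagonal against fp round-off
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationMatrix(names, rho).validate()


def _max_partner(corr: CorrelationMatrix, name: str, pool: list[str]) -> tuple[str, float]:
    """Partner in ``pool`` with the largest |rho| against ``name``."""
    best, best_rho = pool[0], corr.get(name, pool[0])
    for p in pool:
        r = corr.get(name, p)
        if abs(r) > abs(best_rho):
            best, best_rho = p, r
    return best, best_rho


def redundancy_filter(
    corr: CorrelationMatrix,
    threshold: float = 0.7,
    strategy: str = "explicit_list",
    explicit_keep: tuple[str, ...] | None = None,
) -> FilterResult:
    """Prune descriptors whose pairwise |rho| exceeds ``threshold``.

    ``explicit_list`` (default): keep ``explicit_keep`` (the published seven
    by default), remove the rest; each removed descriptor is annotated with
    its max-|rho| partner among the retained ones. ``greedy_degree``:
    iteratively delete the descriptor with the most remaining violating
    pairs (ties: larger mean |rho| among violating pairs, then dictionary
    order, keeping the earlier-listed member of an interchangeable pair)
    until no pair violates. The threshold is strict: |rho| equal to it does
    not trigger removal.
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    corr.validate()
    names = list(corr.names)

    if strategy == "explicit_list":
        keep = list(explicit_keep) if explicit_keep is not None else [
            n for n in names if n in PAPER_RETAINED
        ]
        unknown = [k for k in keep if k not in names]
        if unknown:
            raise ValidationError(f"explicit_keep names not in matrix: {unknown}")
        removed = []
        for n in names:
            if n in keep:
                continue
            partner, rho = _max_partner(corr, n, keep)
            removed.append((n, partner, float(rho)))
        retained = [n for n in names if n in keep]
        return FilterResult(retained, removed, threshold, strategy)

    if strategy != "greedy_degree":
        raise ValidationError(f"unknown strategy {strategy!r}")

    remaining = list(names)
    removed = []
    while True:
        viol = {
            n: [m for m in remaining if m != n and abs(corr.get(n, m)) > threshold]
            for n in remaining
        }
        worst = max(len(v) for v in viol.values()) if remaining else 0
        if worst == 0:
            break
        cands = [n for n in remaining if len(viol[n]) == worst]
        if len(cands) > 1:
            mean_rho = {
                n: np.mean([abs(corr.get(n, m)) for m in viol[n]]) for n in cands
            }
            top = max(mean_rho.values())
            cands = [n for n in cands if mean_rho[n] == top]
        # ties: keep the earlier-listed descriptor, delete the latecomer
        victim = max(cands, key=names.index)
        partner, rho = _max_partner(
            corr, victim, [m for m in remaining if m != victim]
        )
        removed.append((victim, partner, float(rho)))
        remaining.remove(victim)

    return FilterResult(remaining, removed, threshold, "greedy_degree")
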