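"""Exhaustive descriptor-subset search with repeated stratified CV.

Every non-empty subset of the retained descriptors (2^n - 1 models; 127 for
the seven retained ones) is fit with ridge logistic regression under
stratified k-fold cross-validation, scored by the area under the ROC curve
on pooled out-of-fold predictions, repeated over several fold seeds, and
ranked by mean AUC. The frequency of each descriptor among the top-ranked
models identifies the most informative descriptor — the L0 / best-subset
view of sparse model selection.

AUC is computed as the Mann-Whitney statistic: the fraction of
(attractant, non-attractant) pairs in which the attractant scores higher,
ties counted 1/2. Crucially, every subset within a repeat is evaluated on
identical fold assignments so subsets are compared on the same partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from . import logit_core
from .core_data import LabeledTable, ValidationError, register_report_kind

__all__ = [
    "SubsetResult",
    "SearchReport",
    "enumerate_subsets",
    "roc_auc",
    "make_stratified_folds",
    "cross_validate",
    "run_search",
    "top_k_frequency",
]


@register_report_kind
@dataclass
class SubsetResult:
    descriptors: list[str]
    auc_per_repeat: list[float]
    auc_mean: float
    auc_sd: float
    cv_accuracy_mean: float


@register_report_kind
@dataclass
class SearchReport:
    results: list[SubsetResult]   # ranked, best first
    k_folds: int
    seeds: list[int]              # one fold seed per repeat
    frequencies: dict[str, float] # top-10 descriptor frequencies


def enumerate_subsets(descriptors: list[str] | tuple[str, ...]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    names = list(descriptors)
    if not 1 <= len(names) <= 20:
        raise ValidationError("need between 1 and 20 descriptors")
    out: list[tuple[str, ...]] = []
    for k in range(1, len(names) + 1):
        out.extend(sorted(combinations(sorted(names), k)))
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by rank (Mann-Whitney) statistic; ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def make_stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified folds: shuffle within class, deal round-robin.

    Class proportions per fold stay within one compound of the global split.
    If the minority class has fewer than ``k`` members the fold count is
    reduced to that size, with a warning.
    """
    labels = np.asarray(labels).astype(int)
    minority = min(int(labels.sum()), int(len(labels) - labels.sum()))
    if minority == 0:
        raise ValidationError("both classes needed for stratified folds")
    if minority < k:
        warnings.warn(
            f"minority class has {minority} < k={k} members; "
            f"reducing to {minority} folds",
            stacklevel=2,
        )
        k = minority
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _fold_normalizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train-fold z-scoring stats; zero-variance columns pass through."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def cross_validate(
    table: LabeledTable,
    descriptors: tuple[str, ...] | list[str],
    k_folds: int = 10,
    seed: int = 0,
    ridge_lambda: float = 1.0,
    folds: list[np.ndarray] | None = None,
    paper_literal_normalization: bool = False,
) -> tuple[float, float]:
    """Pooled out-of-fold (AUC, accuracy at the 0.5 cutoff).

    Normalization statistics are computed on the training folds only and
    applied to the held-out fold (leakage-safe default). With
    ``paper_literal_normalization`` the whole table is z-scored once before
    splitting, mirroring a normalize-then-cross-validate workflow.
    """
    descriptors = list(descriptors)
    y = table.labels_binary()
    if folds is None:
        folds = make_stratified_folds(y, k_folds, seed)
    X = table.matrix(descriptors)

    if paper_literal_normalization:
        mu, sd = _fold_normalizer(X)
        X = (X - mu) / sd

    oof = np.full(len(y), np.nan)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        Xtr, Xte = X[train_idx], X[test_idx]
        if not paper_literal_normalization:
            mu, sd = _fold_normalizer(Xtr)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        beta, _, _ = logit_core.fit_arrays(Xtr, y[train_idx], ridge_lambda=ridge_lambda)
        oof[test_idx] = expit(Xte @ beta[:-1] + beta[-1])
    auc = roc_auc(oof, y)
    acc = float(np.mean((oof > 0.5).astype(int) == y))
    return auc, acc




def run_search(
    table: LabeledTable,
    descriptors: tuple[str, ...] | list[str],
    k_folds: int = 10,
    repeats: int = 5,
    base_seed: int = 0,
    ridge_lambda: float = 1.0,
    top_k: int = 10,
    paper_literal_normalization: bool = False,
) -> SearchReport:
    """Evaluate every descriptor subset on shared per-repeat partitions."""
    descriptors = list(descriptors)
    y = table.labels_binary()
    seeds = [base_seed + r for r in range(repeats)]
    if repeats == 1:
        warnings.warn("repeats=1: AUC SD reported as 0", stacklevel=2)
    with warnings.catch_warnings():
        # the reduced-folds warning, if any, should fire once, not per subset
        warnings.simplefilter("once")
        fold_sets = [make_stratified_folds(y, k_folds, s) for s in seeds]
    k_eff = len(fold_sets[0])

    results: list[SubsetResult] = []
    for subset in enumerate_subsets(descriptors):
        aucs, accs = [], []
        for folds in fold_sets:
            auc, acc = cross_validate(
                table, subset, ridge_lambda=ridge_lambda, folds=folds,
                paper_literal_normalization=paper_literal_normalization,
            )
            aucs.append(auc)
            accs.append(acc)
        aucs_a = np.asarray(aucs)
        results.append(SubsetResult(
            descriptors=list(subset),
            auc_per_repeat=[float(a) for a in aucs],
            auc_mean=float(aucs_a.mean()),
            auc_sd=float(aucs_a.std(ddof=1)) if repeats > 1 else 0.0,
            cv_accuracy_mean=float(np.mean(accs)),
        ))

    # rank: mean AUC desc; ties -> fewer descriptors, then lexicographic
    results.sort(key=lambda r: (-r.auc_mean, len(r.descriptors), tuple(r.descriptors)))
    report = SearchReport(results=results, k_folds=k_eff, seeds=seeds, frequencies={})
    report.frequencies = top_k_frequency(report, k=min(top_k, len(results)))
    return report


def top_k_frequency(report: SearchReport, k: int = 10) -> dict[str, float]:
    """Fraction of the top-k ranked models containing each descriptor."""
    if k > len(report.results):
        raise ValidationError(
            f"k={k} exceeds the {len(report.results)} ranked models"
        )
    top = report.results[:k]
    all_names = sorted({d for r in report.results for d in r.descriptors})
    return {
        name: sum(name in r.descriptors for r in top) / k for name in all_names
    }
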