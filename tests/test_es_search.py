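"""Exhaustive subset search, ROC/AUC, and stratified cross-validation."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import norm

from chemoqsar import (
    DescriptorSynthConfig,
    ValidationError,
    cross_validate,
    enumerate_subsets,
    roc_auc,
    run_search,
    simulate_descriptor_table,
    top_k_frequency,
)
from chemoqsar.es_search import SearchReport, SubsetResult, make_stratified_folds
from chemoqsar.synthetic_data import TABLE2_CLASS_MOMENTS
from conftest import make_table


def brute_force_auc(scores, labels):
    """Pair-counting oracle: concordant pairs, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEnumerateSubsets:
    def test_seven_descriptors_give_127_models(self):
        assert len(enumerate_subsets(list("ABCDEFG"))) == 127

    def test_singleton(self):
        assert enumerate_subsets(["q-"]) == [("q-",)]

    def test_matches_bitmask_enumeration(self):
        names = ["A", "B", "C"]
        got = enumerate_subsets(names)
        expected = set()
        for mask in range(1, 8):
            expected.add(tuple(sorted(n for i, n in enumerate(names) if mask >> i & 1)))
        assert set(got) == expected
        assert len(got) == 7

    def test_order_by_size_then_lexicographic(self):
        got = enumerate_subsets(["b", "a"])
        assert got == [("a",), ("b",), ("a", "b")]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_subsets([])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_pairs_concordant(self):
        assert roc_auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0]) == 0.75

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties occur
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(np.arange(20, dtype=float))
        labels = np.array([1] * 8 + [0] * 12)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=25)
        labels = np.array([1] * 10 + [0] * 15)
        a0 = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a0)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(a0)

    def test_matches_sklearn(self, rng):
        skm = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            skm.roc_auc_score(labels, scores), abs=1e-12
        )


class TestStratifiedFolds:
    def test_partition_and_balance(self):
        labels = np.array([1] * 38 + [0] * 15)
        folds = make_stratified_folds(labels, 10, seed=3)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(53))
        global_frac = 38 / 53
        for f in folds:
            n_pos = labels[f].sum()
            # class proportions within one compound of the global split
            assert abs(n_pos - global_frac * len(f)) <= 1.0

    def test_small_minority_reduces_fold_count(self):
        labels = np.array([1] * 10 + [0] * 3)
        with pytest.warns(UserWarning, match="reducing"):
            folds = make_stratified_folds(labels, 10, seed=0)
        assert len(folds) == 3

    def test_seed_determinism(self):
        labels = np.array([1] * 20 + [0] * 10)
        f1 = make_stratified_folds(labels, 5, seed=9)
        f2 = make_stratified_folds(labels, 5, seed=9)
        f3 = make_stratified_folds(labels, 5, seed=10)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        assert any(not np.array_equal(a, b) for a, b in zip(f1, f3))


class TestCrossValidate:
    def test_strong_separation_approaches_closed_form(self, rng):
        # class means +/-5, SD 1: population AUC = Phi(10 / sqrt(2)) ~ 1
        x = np.concatenate([rng.normal(5, 1, 50), rng.normal(-5, 1, 50)])
        t = make_table({"x": x}, [1] * 50 + [0] * 50)
        auc, acc = cross_validate(t, ["x"], k_folds=10, seed=1)
        assert norm.cdf(10 / np.sqrt(2)) > 0.999
        assert auc > 0.99
        assert acc > 0.95

    def test_permuted_labels_give_null_auc(self, rng):
        x = rng.normal(size=60)
        aucs = []
        for seed in range(5):
            labels = rng.permutation([1] * 30 + [0] * 30)
            t = make_table({"x": x}, labels)
            auc, _ = cross_validate(t, ["x"], k_folds=10, seed=seed)
            aucs.append(auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_leave_one_out_boundary(self, rng):
        x = rng.normal(size=6)
        t = make_table({"x": x}, [1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning):
            auc, acc = cross_validate(t, ["x"], k_folds=6, seed=0)
        assert np.isfinite(auc) and 0 <= auc <= 1
        assert 0 <= acc <= 1


@pytest.fixture(scope="module")
def planted_table():
    # only q- differs between classes; three descriptors for speed
    moments = {
        "q-": TABLE2_CLASS_MOMENTS["q-"],
        "D": (TABLE2_CLASS_MOMENTS["D"][0], TABLE2_CLASS_MOMENTS["D"][0]),
        "q+": (TABLE2_CLASS_MOMENTS["q+"][0], TABLE2_CLASS_MOMENTS["q+"][0]),
    }
    cfg = DescriptorSynthConfig(seed=5, class_moments=moments)
    return simulate_descriptor_table(cfg)


class TestRunSearch:

    def test_full_seven_descriptor_search_yields_127(self, default_synthetic_table):
        rep = run_search(
            default_synthetic_table,
            list(default_synthetic_table.descriptor_names),
            repeats=2, base_seed=0,
        )
        assert len(rep.results) == 127
        assert all(0 <= r.auc_mean <= 1 and r.auc_sd >= 0 for r in rep.results)
        assert all(len(r.auc_per_repeat) == 2 for r in rep.results)

    def test_planted_signal_recovered(self, planted_table):
        # 3 descriptors -> 7 models; q- appears in 4 of them, so check the
        # top 3 ranked models rather than a top-10 larger than the q- pool
        rep = run_search(planted_table, list(planted_table.descriptor_names),
                         repeats=3, base_seed=2, top_k=3)
        assert "q-" in rep.results[0].descriptors
        assert rep.frequencies["q-"] == 1.0

    def test_same_seed_bit_reproducible(self, planted_table):
        r1 = run_search(planted_table, list(planted_table.descriptor_names),
                        repeats=2, base_seed=4)
        r2 = run_search(planted_table, list(planted_table.descriptor_names),
                        repeats=2, base_seed=4)
        assert [s.auc_per_repeat for s in r1.results] == [s.auc_per_repeat for s in r2.results]
        assert [s.descriptors for s in r1.results] == [s.descriptors for s in r2.results]

    def test_ranking_invariant_to_enumeration_order(self, planted_table):
        names = list(planted_table.descriptor_names)
        r1 = run_search(planted_table, names, repeats=2, base_seed=4)
        r2 = run_search(planted_table, names[::-1], repeats=2, base_seed=4)
        assert [s.descriptors for s in r1.results] == [s.descriptors for s in r2.results]

    def test_single_repeat_warns_and_reports_zero_sd(self, planted_table):
        with pytest.warns(UserWarning, match="repeats=1"):
            rep = run_search(planted_table, ["q-"], repeats=1, base_seed=0)
        assert rep.results[0].auc_sd == 0.0


class TestTopKFrequency:
    def _report(self, subsets):
        results = [
            SubsetResult(list(s), [0.5], 0.5, 0.0, 0.5) for s in subsets
        ]
        return SearchReport(results, 10, [0], {})

    def test_hand_counted_fractions(self):
        rep = self._report([("A",), ("A", "B"), ("B",)])
        freq = top_k_frequency(rep, k=3)
        assert freq == {"A": pytest.approx(2 / 3), "B": pytest.approx(2 / 3)}

    def test_everywhere_and_nowhere(self):
        rep = self._report([("A",), ("A", "B"), ("A", "C"), ("C",)])
        freq = top_k_frequency(rep, k=3)
        assert freq["A"] == 1.0
        # C appears in the 4th-ranked model only, outside the top 3
        assert freq["C"] == pytest.approx(1 / 3)
        rep2 = self._report([("A",), ("A", "B"), ("B",), ("C",)])
        assert top_k_frequency(rep2, k=3)["C"] == 0.0

    def test_k_exceeding_result_count_rejected(self):
        rep = self._report([("A",)])
        with pytest.raises(ValidationError):
            top_k_frequency(rep, k=5)
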