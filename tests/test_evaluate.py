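import numpy as np
import pytest
from conftest import make_dataset
from hypothesis import given
from hypothesis import strategies as st

from ddgeval.data import CANONICAL_GROUPS, annotate_inheritance
from ddgeval.errors import ConfigError, UndefinedStratumError
from ddgeval.evaluate import (
    balanced_auc,
    balanced_resample,
    default_threshold_grid,
    per_gene_auc,
    precision_curve,
    roc_auc,
    stratified_auc,
    threshold_for_precision,
)

scores = st.lists(
    st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0, 3.25]), min_size=1, max_size=8
)


def brute_force_auc(pos, neg):
    """Independent oracle: pairwise counting with half credit for ties."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_mixed_pairs(self):
        # brute force: (2>1), (2<2.5), (3>1), (3>2.5) -> 3/4
        assert roc_auc([2, 3], [1, 2.5]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([5, 6], [1, 2]) == 1.0

    def test_all_ties(self):
        assert roc_auc([1, 1], [1, 1]) == 0.5

    def test_empty_vector_undefined(self):
        with pytest.raises(UndefinedStratumError):
            roc_auc([], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc([np.nan], [1.0])

    @given(scores, scores)
    def test_matches_brute_force(self, pos, neg):
        assert roc_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @given(scores, scores)
    def test_complement_symmetry(self, pos, neg):
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0, abs=1e-12)

    @given(scores, scores)
    def test_scale_invariance(self, pos, neg):
        transform = lambda x: np.exp(3.0 * np.asarray(x)) + 7.0  # strictly increasing
        assert roc_auc(pos, neg) == pytest.approx(
            roc_auc(transform(pos), transform(neg)), abs=1e-12
        )


class TestBalancedResample:
    def test_majority_subsampled_to_minority(self):
        labels = np.array([True] * 3 + [False] * 10)
        plan = balanced_resample(labels, n_reps=100, seed=0)
        for idx in plan.rep_indices:
            assert idx.size == 6
            assert labels[idx].sum() == 3
            assert np.unique(idx).size == idx.size  # without replacement

    def test_pathogenic_majority_is_subsampled(self):
        labels = np.array([True] * 10 + [False] * 4)
        plan = balanced_resample(labels, n_reps=10, seed=0)
        for idx in plan.rep_indices:
            assert labels[idx].sum() == 4 and (~labels[idx]).sum() == 4

    def test_equal_classes_keep_everything(self):
        labels = np.array([True, False, True, False])
        plan = balanced_resample(labels, n_reps=5, seed=1)
        for idx in plan.rep_indices:
            assert sorted(idx) == [0, 1, 2, 3]

    def test_same_seed_identical_plans(self):
        labels = np.array([True] * 3 + [False] * 10)
        a = balanced_resample(labels, n_reps=20, seed=42)
        b = balanced_resample(labels, n_reps=20, seed=42)
        for x, y in zip(a.rep_indices, b.rep_indices):
            np.testing.assert_array_equal(x, y)

    def test_empty_class_undefined(self):
        with pytest.raises(UndefinedStratumError):
            balanced_resample(np.array([True, True]), n_reps=5, seed=0)


def small_dataset(values_by_label, gene="G"):
    rows = []
    for label, values in values_by_label.items():
        for i, v in enumerate(values):
            rows.append((f"{gene}_{label}_{i}", gene, label, {"p": v}))
    return make_dataset(rows, harmonized=True)


class TestBalancedAuc:
    def test_perfect_separation(self):
        ds = small_dataset({"pathogenic": [5, 6], "benign": [1, 2, 3]})
        summary = balanced_auc(ds, "p", n_reps=20, seed=0)
        assert summary.mean_auc == 1.0
        assert summary.sd_auc == 0.0

    def test_equal_classes_no_sampling_freedom(self):
        ds = small_dataset({"pathogenic": [2, 3, 1], "benign": [1.5, 2.5, 0.5]})
        summary = balanced_auc(ds, "p", n_reps=50, seed=0)
        pos = np.array([2, 3, 1.0])
        neg = np.array([1.5, 2.5, 0.5])
        assert summary.sd_auc == 0.0
        assert summary.mean_auc == roc_auc(pos, neg)

    def test_missing_dropped_before_planning(self):
        rows = [
            ("v1", "G", "pathogenic", {"p": 3.0}),
            ("v2", "G", "pathogenic", {}),
            ("v3", "G", "benign", {"p": 1.0}),
            ("v4", "G", "benign", {"p": 2.0}),
        ]
        ds = make_dataset(rows, harmonized=True)
        summary = balanced_auc(ds, "p", n_reps=30, seed=0)
        assert summary.n_pos == 1 and summary.n_neg == 2
        # each rep: 1 pathogenic vs 1 benign, both with scores
        assert set(np.round(summary.per_rep, 6)) <= {0.0, 0.5, 1.0}

    def test_reproducible(self):
        ds = small_dataset({"pathogenic": [5, 2, 3], "benign": [1, 2, 3, 4, 0.5]})
        a = balanced_auc(ds, "p", n_reps=40, seed=7)
        b = balanced_auc(ds, "p", n_reps=40, seed=7)
        np.testing.assert_array_equal(a.per_rep, b.per_rep)

    def test_uses_absolute_values(self):
        ds = small_dataset({"pathogenic": [-5, -6], "benign": [1, 2]})
        assert balanced_auc(ds, "p", n_reps=5, seed=0).mean_auc == 1.0


class TestStratifiedAuc:
    def make(self):
        rows = []
        for gene, label, values in [
            ("HIG", "pathogenic", [4, 5]),
            ("HIG", "benign", [1, 2]),
            ("OTH", "pathogenic", [2, 3]),
            ("OTH", "benign", [1, 4]),
        ]:
            for i, v in enumerate(values):
                rows.append((f"{gene}_{label}_{i}", gene, label, {"p": v}))
        ds = make_dataset(rows, harmonized=True)
        flags = annotate_inheritance(ds, hi={"HIG"}, ad=set(), ar=set())
        return ds, flags

    def test_group_and_complement(self):
        ds, flags = self.make()
        group, comp = stratified_auc(
            ds, "p", CANONICAL_GROUPS["haploinsufficient"], flags, n_reps=10, seed=0
        )
        assert group.stratum == "haploinsufficient"
        assert group.mean_auc == 1.0  # HI gene perfectly separated, balanced
        assert comp.stratum == "not_haploinsufficient"
        assert comp.mean_auc == roc_auc([2, 3], [1, 4])

    def test_degenerate_predicate_complement_undefined(self):
        ds, _ = self.make()
        flags = annotate_inheritance(ds, hi={"HIG", "OTH"}, ad=set(), ar=set())
        group, comp = stratified_auc(
            ds, "p", CANONICAL_GROUPS["haploinsufficient"], flags, n_reps=10, seed=0
        )
        assert comp is None
        # everything in the group and classes balanced -> exact whole-data AUC
        whole = balanced_auc(ds, "p", n_reps=10, seed=1)
        assert group.mean_auc == whole.mean_auc

    def test_missing_flags_error(self):
        ds, flags = self.make()
        with pytest.raises(ConfigError):
            stratified_auc(
                ds, "p", CANONICAL_GROUPS["haploinsufficient"], flags.drop("OTH"), n_reps=2, seed=0
            )


class TestPerGeneAuc:
    def test_skips_gene_without_pathogenic(self):
        rows = [
            ("v1", "G1", "benign", {"p": 1.0}),
            ("v2", "G1", "benign", {"p": 2.0}),
            ("v3", "G2", "pathogenic", {"p": 3.0}),
            ("v4", "G2", "benign", {"p": 1.0}),
        ]
        ds = make_dataset(rows, harmonized=True)
        results, skipped = per_gene_auc(ds, "p", n_reps=5, seed=0)
        assert "G1" in skipped and "G1" not in results
        assert results["G2"].mean_auc == 1.0

    def test_duplicated_gene_content_identical_rows(self):
        # same balanced content under two gene names -> identical summaries
        rows = []
        for gene in ("GA", "GB"):
            rows += [
                (f"{gene}_p0", gene, "pathogenic", {"p": 4.0}),
                (f"{gene}_p1", gene, "pathogenic", {"p": 2.0}),
                (f"{gene}_b0", gene, "benign", {"p": 1.0}),
                (f"{gene}_b1", gene, "benign", {"p": 3.0}),
            ]
        ds = make_dataset(rows, harmonized=True)
        results, _ = per_gene_auc(ds, "p", n_reps=7, seed=0)
        np.testing.assert_array_equal(results["GA"].per_rep, results["GB"].per_rep)

    def test_min_per_class(self):
        rows = [
            ("v1", "G1", "pathogenic", {"p": 3.0}),
            ("v2", "G1", "benign", {"p": 1.0}),
        ]
        ds = make_dataset(rows, harmonized=True)
        _, skipped = per_gene_auc(ds, "p", n_reps=2, seed=0, min_per_class=2)
        assert "G1" in skipped


class TestPrecisionCurve:
    def test_balanced_prevalence_at_zero(self):
        ds = small_dataset({"pathogenic": [5, 4, 3], "benign": [3, 2, 1, 0.5, 6]})
        curve = precision_curve(ds, "p", n_reps=25, seed=0)
        assert curve.thresholds[0] == 0.0
        assert curve.precision[0] == 0.5  # balanced design, closed lower bound
        assert curve.n_reps_contributing[0] == 25

    def test_direct_count(self):
        ds = small_dataset({"pathogenic": [5, 4], "benign": [3, 2]})
        curve = precision_curve(ds, "p", thresholds=np.array([3.5]), n_reps=5, seed=0)
        assert curve.precision.tolist() == [1.0]
        assert curve.n_above.tolist() == [2.0]

    def test_threshold_boundary_is_closed(self):
        ds = small_dataset({"pathogenic": [2.0], "benign": [1.0]})
        curve = precision_curve(ds, "p", thresholds=np.array([1.0, 2.0]), n_reps=3, seed=0)
        # at t=1.0 both records count (>= t); at t=2.0 only the pathogenic one
        assert curve.precision.tolist() == [0.5, 1.0]
        assert curve.n_above.tolist() == [2.0, 1.0]

    def test_unsupported_points_absent(self):
        ds = small_dataset({"pathogenic": [2.0], "benign": [1.0]})
        curve = precision_curve(ds, "p", thresholds=np.array([0.0, 50.0]), n_reps=3, seed=0)
        assert curve.thresholds.tolist() == [0.0]

    def test_all_unsupported_warns_empty(self):
        ds = small_dataset({"pathogenic": [2.0], "benign": [1.0]})
        with pytest.warns(UserWarning, match="no supported points"):
            curve = precision_curve(ds, "p", thresholds=np.array([99.0]), n_reps=3, seed=0)
        assert curve.thresholds.size == 0

    def test_unbalanced_mode_uses_full_stratum(self):
        ds = small_dataset({"pathogenic": [5.0], "benign": [1.0, 2.0, 3.0]})
        curve = precision_curve(ds, "p", thresholds=np.array([0.0]), balanced=False)
        assert curve.precision.tolist() == [0.25]  # raw prevalence

    def test_invalid_grid_rejected(self):
        ds = small_dataset({"pathogenic": [2.0], "benign": [1.0]})
        with pytest.raises(ConfigError):
            precision_curve(ds, "p", thresholds=np.array([2.0, 1.0]), n_reps=2, seed=0)

    def test_reproducible(self):
        ds = small_dataset({"pathogenic": [5, 4, 3], "benign": [3, 2, 1, 0.5, 6, 7]})
        a = precision_curve(ds, "p", n_reps=20, seed=3)
        b = precision_curve(ds, "p", n_reps=20, seed=3)
        np.testing.assert_array_equal(a.precision, b.precision)
        np.testing.assert_array_equal(a.n_above, b.n_above)


class TestThresholdForPrecision:
    def curve(self):
        ds = small_dataset({"pathogenic": [5, 4], "benign": [1, 2]})
        return precision_curve(ds, "p", thresholds=np.array([0.0, 3.0]), n_reps=4, seed=0)

    def test_target_below_first_point(self):
        hit = threshold_for_precision(self.curve(), 0.4, min_support=1)
        assert hit.threshold == 0.0

    def test_reachable_target(self):
        hit = threshold_for_precision(self.curve(), 0.9, min_support=1)
        assert hit.threshold == 3.0
        assert hit.precision == 1.0

    def test_unreachable_returns_none(self):
        ds = small_dataset({"pathogenic": [2, 1], "benign": [2, 1]})
        curve = precision_curve(ds, "p", thresholds=np.array([0.0, 1.0]), n_reps=4, seed=0)
        assert threshold_for_precision(curve, 0.999, min_support=1) is None

    def test_target_out_of_range(self):
        with pytest.raises(ConfigError):
            threshold_for_precision(self.curve(), 1.5, min_support=1)

    def test_min_support_filters(self):
        hit = threshold_for_precision(self.curve(), 0.9, min_support=3)
        assert hit is None  # only 2 records above 3.0


def test_default_threshold_grid():
    grid = default_threshold_grid(0.35, step=0.1)
    np.testing.assert_allclose(grid, [0.0, 0.1, 0.2, 0.3])
    assert default_threshold_grid(0.0).tolist() == [0.0]
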