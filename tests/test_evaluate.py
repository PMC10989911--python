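import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panfactor import (
    ConfusionCounts,
    PangenomeStats,
    StrainGeneContent,
    ValidationError,
    annotate_strains,
    confusion_counts,
    filter_composition,
    jaccard_distance,
    jsd,
    match_strains,
    mcc,
    pr_auprc,
    random_profile_baseline,
)


def _random_composition(rng, size):
    return rng.dirichlet(np.ones(size))


class TestJSD:
    def test_identical_composition_is_zero(self):
        assert jsd([0.6, 0.4], [0.6, 0.4]) == 0.0

    def test_zero_padding_identity(self):
        assert jsd([1.0], [1.0, 0.0]) == 0.0

    def test_hand_computed_value(self):
        # (1, 0) vs (0.5, 0.5): mixture (0.75, 0.25),
        # JSD = H(0.75, 0.25) - H(0.5, 0.5)/2 = 0.81128 - 0.5
        assert jsd([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.311278, abs=1e-5)

    def test_sorted_convention_collapses_permutations(self):
        # after descending sort, (1,0) and (0,1) are the same profile
        assert jsd([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_point_mass_vs_uniform_is_large_but_within_bound(self):
        value = jsd([1.0] + [0.0] * 7, [0.125] * 8)
        assert 0.7 <= value <= 1.0

    def test_sorting_makes_order_irrelevant(self):
        assert jsd([0.3, 0.7], [0.7, 0.3]) == 0.0

    @given(seed=st.integers(0, 5000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_composition(rng, int(rng.integers(1, 8)))
        b = _random_composition(rng, int(rng.integers(1, 8)))
        assert jsd(a, b) == pytest.approx(jsd(b, a), abs=1e-12)
        assert 0.0 <= jsd(a, b) <= 1.0

    def test_not_a_composition_rejected(self):
        with pytest.raises(ValidationError, match="sums to"):
            jsd([0.5, 0.4], [0.5, 0.5])

    def test_filter_composition_drops_and_rescales(self):
        out = filter_composition([0.495, 0.5, 0.005])
        np.testing.assert_allclose(out, [0.495 / 0.995, 0.5 / 0.995])


class TestMCC:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=3, tn=5, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=0, tn=0, fp=4, fn=4), -1.0),
            (ConfusionCounts(tp=1, tn=1, fp=1, fn=1), 0.0),
            (ConfusionCounts(tp=5, tn=0, fp=3, fn=0), 0.0),  # degenerate denominator
        ],
    )
    def test_reference_values(self, counts, expected):
        assert mcc(counts) == pytest.approx(expected)

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_swap_invariance_and_bounds(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        a = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a == pytest.approx(b)
        assert -1.0 <= a <= 1.0

    def test_confusion_counts_from_vectors(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_distance({1, 2}, {1, 2}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_distance({1}, {2, 3}) == 1.0

    def test_partial_overlap(self):
        assert jaccard_distance({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_binary_vectors_accepted(self):
        assert jaccard_distance([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            jaccard_distance(set(), [0, 0])


def _content_from_presence(presence, theta=0.5):
    presence = np.asarray(presence, dtype=np.int8)
    n, k = presence.shape
    return StrainGeneContent(
        family_ids=[f"gf{i}" for i in range(n)],
        strain_ids=[f"strain{j + 1}" for j in range(k)],
        raw_weights=presence.astype(float),
        presence=presence,
        confidence=np.ones((n, k)),
        theta=np.full(k, theta),
        p_max=np.full(k, 2 * theta),
    )


class TestAnnotation:
    def test_exact_match_annotated_at_zero_distance(self, toy_stats):
        presence = toy_stats.membership[:, [1]]
        ann = annotate_strains(_content_from_presence(presence), toy_stats)
        assert ann[0].genome_id == "g2"
        assert ann[0].distance == 0.0

    def test_nearest_genome_wins(self):
        membership = np.array([[1, 1], [1, 1], [1, 0], [0, 1], [0, 1]])
        stats = PangenomeStats([f"gf{i}" for i in range(5)], ["g1", "g2"], membership)
        profile = np.array([[1], [1], [1], [0], [0]])  # equals g1
        ann = annotate_strains(_content_from_presence(profile), stats)
        assert ann[0].genome_id == "g1"
        assert ann[0].distance == 0.0

    def test_tie_reported_with_lexicographic_primary(self):
        membership = np.array([[1, 1], [1, 1], [1, 0], [0, 1]])
        stats = PangenomeStats([f"gf{i}" for i in range(4)], ["g3", "g1"], membership)
        profile = np.array([[1], [1], [0], [0]])  # distance 1/3 to both genomes
        ann = annotate_strains(_content_from_presence(profile), stats)
        assert ann[0].genome_id == "g1"
        assert ann[0].ties == ["g1", "g3"]

    def test_empty_profile_rejected(self, toy_stats):
        content = _content_from_presence(np.zeros((60, 1), dtype=int))
        with pytest.raises(ValidationError, match="empty"):
            annotate_strains(content, toy_stats)


class TestMatching:
    def test_permutation_recovered(self):
        rng = np.random.default_rng(0)
        truth = (rng.random((50, 3)) < 0.5).astype(int)
        perm = [2, 0, 1]
        matching = match_strains(truth[:, perm], truth)
        assert {(i, j) for i, j, _ in matching.pairs} == {(0, 2), (1, 0), (2, 1)}
        assert all(d == 0.0 for _, _, d in matching.pairs)

    def test_extra_predictions_grouped(self):
        rng = np.random.default_rng(1)
        truth = (rng.random((60, 4)) < 0.5).astype(int)
        extra = (rng.random((60, 1)) < 0.5).astype(int)
        matching = match_strains(np.hstack([truth, extra]), truth)
        assert len(matching.pairs) == 4
        assert matching.extras == [4]
        assert matching.missing == []

    def test_symmetric_tie_broken_toward_low_predicted_index(self):
        profile = np.array([[1], [1], [0], [0]])
        pred = np.hstack([profile, profile])
        truth = np.hstack([profile, profile])
        matching = match_strains(pred, truth)
        assert (0, 0, 0.0) in matching.pairs and (1, 1, 0.0) in matching.pairs


def _brute_force_pr(confidence, calls, truth):
    """Independent oracle: enumerate every distinct signed-score threshold."""
    confidence = np.asarray(confidence, dtype=float)
    calls = np.asarray(calls).astype(bool)
    truth = np.asarray(truth).astype(bool)
    scores = np.where(calls, confidence, -confidence)
    points = []
    for t in sorted(set(scores.tolist()), reverse=True):
        called = scores >= t
        tp = int(np.sum(called & truth))
        points.append((tp / truth.sum(), tp / called.sum()))
    recalls = [0.0] + [r for r, _ in points]
    precisions = [points[0][1]] + [p for _, p in points]
    area = 0.0
    for i in range(1, len(recalls)):
        area += 0.5 * (precisions[i] + precisions[i - 1]) * (recalls[i] - recalls[i - 1])
    return points, area


class TestPRCurve:
    def test_perfect_prediction_gives_unit_area(self):
        truth = np.array([1, 1, 0, 1, 0])
        curve = pr_auprc(np.ones(5), truth, truth)
        assert curve.auprc == pytest.approx(1.0)

    def test_recall_non_decreasing(self):
        rng = np.random.default_rng(0)
        conf = rng.random(30)
        calls = rng.random(30) < 0.5
        truth = rng.random(30) < 0.4
        curve = pr_auprc(conf, calls, truth)
        assert np.all(np.diff(curve.recall) >= 0)

    @given(seed=st.integers(0, 2000))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        truth = rng.random(n) < 0.5
        if not truth.any():
            truth[0] = True
        calls = rng.random(n) < 0.5
        conf = np.round(rng.random(n), 2)  # rounded scores force ties
        curve = pr_auprc(conf, calls, truth)
        _, expected_area = _brute_force_pr(conf, calls, truth)
        assert curve.auprc == pytest.approx(expected_area, abs=1e-12)

    def test_all_absent_truth_rejected(self):
        with pytest.raises(ValidationError, match="recall undefined"):
            pr_auprc(np.ones(4), np.ones(4), np.zeros(4))

    def test_signed_ranking_orders_present_before_absent(self):
        # confident-present ranks above confident-absent despite equal confidence
        conf = np.array([1.0, 1.0])
        calls = np.array([1, 0])
        truth = np.array([1, 0])
        curve = pr_auprc(conf, calls, truth)
        assert curve.auprc == pytest.approx(1.0)


class TestRandomBaseline:
    def test_mean_auprc_tracks_truth_prevalence(self):
        rng = np.random.default_rng(8)
        n = 600
        membership = (rng.random((n, 3)) < 0.4).astype(int)
        stats = PangenomeStats([f"gf{i}" for i in range(n)], ["g1", "g2", "g3"], membership)
        truth = rng.random(n) < 0.4
        base = random_profile_baseline(stats, truth, n_draws=200, seed=1)
        assert base.shape == (200,)
        assert np.mean(base) == pytest.approx(truth.mean(), abs=0.05)

    def test_reproducible_given_seed(self, toy_stats):
        truth = np.zeros(60, dtype=int)
        truth[:30] = 1
        a = random_profile_baseline(toy_stats, truth, n_draws=20, seed=4)
        b = random_profile_baseline(toy_stats, truth, n_draws=20, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_oversized_expected_count_rejected(self):
        stats = PangenomeStats(["gf1", "gf2"], ["g1"], np.array([[1], [1]]))
        stats.g_expected = 5.0
        with pytest.raises(ValidationError, match="pangenome size"):
            random_profile_baseline(stats, np.array([1, 0]), n_draws=1, seed=0)
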