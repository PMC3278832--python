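import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcindex import (BackgroundComposition, ClusterSet, beta, beta_strength,
                     classify_mp, highly_monochromatic, mp_score,
                     score_population, smci)
from mcindex.scores import MPResult

from conftest import make_cluster, make_cluster_counts


def population(count_pairs, magnitude=0.2):
    clusters = [make_cluster_counts(p, n, magnitude, cluster_id=f"c{i}")
                for i, (p, n) in enumerate(count_pairs)]
    return ClusterSet(clusters, min_interactions=1)


class TestBeta:
    @pytest.mark.parametrize("n_pos,n_neg,expected", [
        (0, 15, -1.0),            # pure negative, e.g. an all-negative complex
        (5, 6, -1 / 11),
        (144, 19, 125 / 163),     # strongly positive large cluster
    ])
    def test_signed_count_purity(self, n_pos, n_neg, expected):
        assert beta(make_cluster_counts(n_pos, n_neg)) == pytest.approx(expected)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            beta(make_cluster([]))

    def test_beta_strength_needs_signal(self):
        with pytest.raises(ValueError):
            beta_strength(make_cluster([1e-15, -1e-15]))


class TestMci:
    def test_single_pure_cluster_is_one(self):
        assert score_population(population([(5, 0)])).mci == 1.0

    def test_weighted_mean(self):
        # sizes 4 (beta 1) and 6 (beta 0) -> (4*1 + 6*0) / 10
        pop = score_population(population([(4, 0), (3, 3)]))
        assert pop.mci == pytest.approx(0.4)

    def test_balanced_clusters_are_zero(self):
        pop = score_population(population([(2, 2), (3, 3)]))
        assert pop.mci == 0.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            score_population(ClusterSet([], min_interactions=1))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12))
                    .filter(lambda t: sum(t) >= 1), min_size=1, max_size=10))
    def test_brute_force_oracle(self, counts):
        pop = score_population(population(counts))
        num = sum(abs(p - n) for p, n in counts)
        den = sum(p + n for p, n in counts)
        assert pop.mci == pytest.approx(num / den)
        assert 0 <= pop.mci <= 1

    def test_invariant_under_ordering_and_sign_flip(self):
        counts = [(3, 1), (0, 5), (2, 2), (7, 1)]
        base = score_population(population(counts)).mci
        shuffled = score_population(population(counts[::-1])).mci
        flipped = score_population(population([(n, p) for p, n in counts])).mci
        assert base == pytest.approx(shuffled) == pytest.approx(flipped)

    def test_split_cluster_preserves_mci(self):
        # splitting a cluster into parts with identical beta is a no-op
        whole = score_population(population([(6, 2), (1, 3)])).mci
        split = score_population(population([(3, 1), (3, 1), (1, 3)])).mci
        assert whole == pytest.approx(split)


class TestSmci:
    def test_cancellation(self):
        pop = ClusterSet([make_cluster([0.2, -0.2])], min_interactions=1)
        assert smci(pop) == pytest.approx(0.0)

    def test_all_positive_is_one(self):
        pop = ClusterSet([make_cluster([0.1, 0.4, 0.2])], min_interactions=1)
        assert smci(pop) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.lists(st.sampled_from([1, -1]), min_size=1, max_size=6),
                    min_size=1, max_size=5))
    def test_equal_magnitudes_reduce_to_mci(self, sign_patterns):
        clusters = [make_cluster([0.3 * s for s in signs], cluster_id=f"c{i}")
                    for i, signs in enumerate(sign_patterns)]
        pop = score_population(ClusterSet(clusters, min_interactions=1))
        assert pop.smci == pytest.approx(pop.mci)


class TestMpScore:
    bg = BackgroundComposition(40, 60)  # f0 = 0.4

    def test_contract_endpoints(self):
        assert mp_score(make_cluster_counts(7, 0), self.bg).mp == 1.0
        assert mp_score(make_cluster_counts(0, 7), self.bg).mp == -1.0

    def test_zero_at_background_ratio(self):
        assert mp_score(make_cluster_counts(4, 6), self.bg).mp == pytest.approx(0.0)

    def test_monotone_in_positive_fraction(self):
        scores = [mp_score(make_cluster_counts(k, 10 - k), self.bg).mp
                  for k in range(11)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_degenerate_background(self):
        degenerate = BackgroundComposition(10, 0)
        # pure clusters still score, mixed ones are undefined
        assert mp_score(make_cluster_counts(3, 0), degenerate).mp == 1.0
        with pytest.raises(ValueError):
            mp_score(make_cluster_counts(2, 1), degenerate)


class TestClassification:
    def test_strict_threshold(self):
        results = [MPResult("a", 0.51, True, "positive"),
                   MPResult("b", 0.5, False, "none"),
                   MPResult("c", -0.7, True, "negative")]
        counts = classify_mp(results)
        assert (counts.positive, counts.negative, counts.non_monochromatic) \
            == (1, 1, 1)

    def test_direction_computed_by_mp_score(self):
        bg = BackgroundComposition(25, 75)  # f0 = 0.25
        # f = 0.625 gives mp = (0.625 - 0.25) / 0.75 = 0.5 exactly: not counted
        boundary = mp_score(make_cluster_counts(5, 3), bg)
        assert boundary.mp == pytest.approx(0.5)
        assert not boundary.monochromatic and boundary.direction == "none"


class TestHighlyMonochromatic:
    def test_strictly_above_mci(self):
        pop = score_population(population([(0, 4), (3, 3)]))
        assert pop.mci == pytest.approx(0.4)
        subset = highly_monochromatic(pop)
        assert [s.cluster_id for s in subset.members] == ["c0"]
        assert (subset.n_positive, subset.n_negative) == (0, 1)

    def test_equality_excluded(self):
        # every cluster has |beta| = 0.5 = mci exactly -> none strictly above
        pop = score_population(population([(3, 1), (1, 3)]))
        assert pop.mci == pytest.approx(0.5)
        assert highly_monochromatic(pop).members == ()

    def test_all_pure_population_has_none(self):
        pop = score_population(population([(4, 0), (0, 3)]))
        assert pop.mci == 1.0
        assert highly_monochromatic(pop).members == ()
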