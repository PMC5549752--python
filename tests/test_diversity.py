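"""Closed-form diversity statistics against hand-computed and library oracles."""

import numpy as np
import pytest
from skbio.diversity.alpha import ace as skbio_ace
from skbio.diversity.alpha import gini_index as skbio_gini
from skbio.diversity.alpha import shannon as skbio_shannon

from cloudotu.diversity import (
    ace,
    chao1,
    coverage_ratio,
    diversity_report,
    gini,
    goods_coverage,
    lorenz,
    rarefaction_exact,
    rarefy,
    shannon,
)


def random_counts(rng, n=40):
    return rng.integers(0, 50, size=n) + (rng.random(n) < 0.3)


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([10]) == 0.0

    def test_uniform_is_log_n(self):
        assert shannon([7] * 12) == pytest.approx(np.log(12))

    def test_hand_computed(self):
        assert shannon([1, 2, 3]) == pytest.approx(1.0114, abs=1e-4)

    def test_matches_skbio(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = random_counts(rng)
            if x.sum() == 0:
                continue
            assert shannon(x) == pytest.approx(skbio_shannon(x, base=np.e))

    def test_invariances(self):
        x = [5, 1, 9, 3]
        assert shannon(x) == pytest.approx(shannon(x[::-1]))
        assert shannon(x) == pytest.approx(shannon([10 * v for v in x]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestAce:
    def test_no_rare_taxa(self):
        assert ace([11, 12]) == 2.0

    def test_hand_computed(self):
        # S_abund=1, S_rare=3, N_rare=4, F1=2, C=0.5, gamma2=0 -> 1 + 6 + 0
        assert ace([1, 1, 2, 15]) == pytest.approx(7.0)

    def test_chao1_fallback_when_all_rare_are_singletons(self):
        x = [1, 1, 1, 20]
        assert ace(x) == pytest.approx(chao1(x))

    def test_lower_bounded_by_observed(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = random_counts(rng)
            x = x[x > 0]
            if len(x) == 0 or (x[x <= 10] == 1).all():
                continue
            assert ace(x) >= (x > 0).sum() - 1e-9

    def test_matches_skbio(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = random_counts(rng)
            x = x[x > 0]
            rare = x[x <= 10]
            if len(rare) == 0 or (rare == 1).all():
                continue
            assert ace(x) == pytest.approx(skbio_ace(x))


class TestGiniLorenz:
    def test_uniform_zero(self):
        assert gini([5, 5, 5, 5]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert gini([1, 2, 3, 4]) == pytest.approx(0.25)

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(1, 100, size=20)
            g = gini(x)
            assert 0 <= g <= 1 - 1 / 20 + 1e-12
            assert gini(3 * x) == pytest.approx(g)

    def test_matches_skbio_trapezoid(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.integers(1, 100, size=30)
            assert gini(x) == pytest.approx(skbio_gini(x, method="trapezoids"))

    def test_lorenz_endpoints_and_convexity(self):
        otus, reads = lorenz([4, 1, 7, 2, 9])
        assert (otus[0], reads[0]) == (0.0, 0.0)
        assert (otus[-1], reads[-1]) == (1.0, 1.0)
        increments = np.diff(reads)
        assert np.all(np.diff(increments) >= -1e-12)  # convex
        assert np.all(reads <= otus + 1e-12)  # under the diagonal


class TestCoverage:
    @pytest.mark.parametrize(
        "observed,estimated,expected_pct",
        [(7_793, 10_802, 72.1), (20_432, 20_954, 97.5)],
    )
    def test_published_richness_pairs(self, observed, estimated, expected_pct):
        assert 100 * coverage_ratio(observed, estimated) == pytest.approx(
            expected_pct, abs=0.05
        )

    def test_exact_estimate_gives_one(self):
        assert coverage_ratio(100, 100) == 1.0

    def test_nonpositive_estimate_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio(10, 0)

    def test_goods_coverage(self):
        # 2 singletons out of 12 reads
        assert goods_coverage([1, 1, 4, 6]) == pytest.approx(1 - 2 / 12)


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        x = [5, 3, 9, 1]
        curve = rarefaction_exact(x, [18])
        assert curve.expected_richness[0] == pytest.approx(4.0)

    def test_depth_one_gives_one(self):
        curve = rarefaction_exact([5, 3, 9], [1])
        assert curve.expected_richness[0] == pytest.approx(1.0)

    def test_hand_computed_hypergeometric(self):
        curve = rarefaction_exact([5, 5], [2])
        assert curve.expected_richness[0] == pytest.approx(14 / 9)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(6)
        x = rng.integers(1, 40, size=25)
        depths = list(range(1, int(x.sum()) + 1, 25))
        rich = rarefaction_exact(x, depths).expected_richness
        assert all(b >= a - 1e-9 for a, b in zip(rich, rich[1:]))

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_exact([2, 2], [5])

    def test_large_totals_no_overflow(self):
        x = np.full(1000, 10_000)
        rich = rarefaction_exact(x, [1_000_000]).expected_richness[0]
        assert 0 < rich <= 1000


class TestRarefy:
    def test_full_depth_returns_input(self):
        x = np.array([5, 0, 7])
        assert rarefy(x, 12, seed=0).tolist() == [5, 0, 7]

    def test_depth_zero(self):
        assert rarefy([5, 7], 0, seed=0).tolist() == [0, 0]

    def test_sum_and_reproducibility(self):
        x = np.arange(10) * 3
        a = rarefy(x, 40, seed=42)
        b = rarefy(x, 40, seed=42)
        assert a.sum() == 40 and np.array_equal(a, b)
        assert np.all(a <= x)

    def test_monte_carlo_mean_matches_exact(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 20, size=30)
        depth = int(x.sum() // 3)
        exact = rarefaction_exact(x, [depth]).expected_richness[0]
        reps = 3000
        obs = np.array(
            [(rarefy(x, depth, rng) > 0).sum() for _ in range(reps)], dtype=float
        )
        se = obs.std(ddof=1) / np.sqrt(reps)
        assert abs(obs.mean() - exact) <= 3 * se + 1e-9


class TestReport:
    def test_report_consistency(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 30, size=50)
        rep = diversity_report(x, label="s1_DNA")
        assert rep.observed_richness == int((x > 0).sum())
        assert rep.coverage == pytest.approx(rep.observed_richness / rep.ace)
        assert 0 <= rep.shannon_h <= np.log(rep.observed_richness) + 1e-9
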