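import numpy as np
import pytest

from mblasso.config import MblassoConfig
from mblasso.data_model import PhenotypeVector, ScreenResult
from mblasso.screening import (
    isis_iteration,
    pearson_scores,
    screen,
    sis_scad,
    top_select,
    union_candidates,
)
from mblasso import simulator as sim


class TestPearsonScores:
    def test_affine_copy_scores_one(self):
        x = np.array([[1], [0], [-1], [0], [1]], dtype=float)
        y = 3.0 * x[:, 0] + 7.0
        assert pearson_scores(x, y)[0] == pytest.approx(1.0)

    def test_negated_copy_scores_minus_one(self):
        x = np.array([[1], [0], [-1], [1]], dtype=float)
        assert pearson_scores(x, -2.0 * x[:, 0])[0] == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        x = np.array([[1], [1], [-1], [-1]], dtype=float)
        y = np.array([3.0, 1.0, 1.0, -1.0])
        assert pearson_scores(x, y)[0] == pytest.approx(np.sqrt(0.5))

    def test_constant_column_scores_zero_with_warning(self):
        X = np.column_stack([np.ones(4), [1, 0, -1, 0]])
        with pytest.warns(UserWarning, match="constant SNP"):
            w = pearson_scores(X, np.array([1.0, 2.0, 3.0, 4.0]))
        assert w[0] == 0.0

    def test_constant_phenotype_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_scores(np.eye(3), np.ones(3))

    def test_invariant_to_positive_affine_phenotype_map(self, rng):
        X = rng.integers(-1, 2, size=(50, 20)).astype(float)
        y = rng.normal(size=50)
        w1 = pearson_scores(X, y)
        w2 = pearson_scores(X, 3.5 * y + 11.0)
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestTopSelect:
    def test_plain_top_three(self):
        idx = top_select(np.array([.9, .5, .4, .3, .1]), n=4)
        assert sorted(idx) == [0, 1, 2]

    def test_ties_at_cutoff_all_included(self):
        idx = top_select(np.array([.9, .5, .5, .5, .1]), n=4)
        assert sorted(idx) == [0, 1, 2, 3]

    def test_small_panel_keeps_all_with_warning(self):
        with pytest.warns(UserWarning, match="keeping all"):
            idx = top_select(np.array([.2, .1]), n=10)
        assert sorted(idx) == [0, 1]

    def test_absolute_vs_raw_ranking(self):
        scores = np.array([-0.9, 0.5, 0.1])
        assert 0 in top_select(scores, n=2, use_absolute=True)
        assert 0 not in top_select(scores, n=2, use_absolute=False)


class TestSisScad:
    def test_strong_qtn_selected(self, small_panel):
        G, y, qtn, _ = small_panel
        type_i, fit, scores = sis_scad(G.X, y, "pearson")
        assert qtn[0] in type_i  # the h2=0.3 locus

    def test_pure_noise_may_select_nothing(self, rng):
        X = rng.integers(-1, 2, size=(60, 30)).astype(float)
        y = rng.normal(size=60)
        type_i, fit, _ = sis_scad(X, y, "pearson")
        assert type_i.size <= 3  # near-null fit on unscreenable noise

    def test_small_panel_reduces_to_scad_on_all(self, rng):
        X = rng.integers(-1, 2, size=(100, 5)).astype(float)
        y = 2.0 * X[:, 2] + rng.normal(size=100)
        with pytest.warns(UserWarning, match="keeping all"):
            type_i, _, scores = sis_scad(X, y, "pearson")
        assert 2 in type_i and scores.size == 5


class TestIsisIteration:
    def test_masked_qtn_revived(self):
        """A locus whose marginal signal is cancelled by a correlated locus
        reappears after the Type-I contribution is subtracted."""
        rng = np.random.default_rng(42)
        n = 300
        a = rng.integers(-1, 2, size=n).astype(float)
        b = np.where(rng.random(n) < 0.8, a, rng.integers(-1, 2, size=n))
        noise_cols = rng.integers(-1, 2, size=(n, 60)).astype(float)
        X = np.column_stack([a, b, noise_cols])
        # b's effect opposes a's so b is marginally near-silent
        y = 2.0 * a - 1.4 * b + rng.normal(size=n)
        cfg = MblassoConfig()
        type_i, fit, _ = sis_scad(X, y, "pearson", cfg)
        type_ii, _ = isis_iteration(X, y, type_i, fit, "pearson", cfg)
        assert {0, 1} <= set(type_i) | set(type_ii)
        assert not set(type_i) & set(type_ii)

    def test_empty_type_i_rerun_equals_plain_sis(self, small_panel):
        G, y, _, _ = small_panel
        type_i0, fit, _ = sis_scad(G.X, y, "pearson")
        empty = np.array([], dtype=int)
        type_ii, y2 = isis_iteration(G.X, y, empty, fit, "pearson")
        np.testing.assert_allclose(y2, y.values)
        np.testing.assert_array_equal(np.sort(type_ii), np.sort(type_i0))

    def test_all_snps_in_type_i_returns_empty(self, rng):
        X = rng.integers(-1, 2, size=(30, 4)).astype(float)
        y = rng.normal(size=30)
        _, fit, _ = sis_scad(X, y, "pearson")
        type_ii, _ = isis_iteration(X, y, np.arange(4), fit, "pearson")
        assert type_ii.size == 0


class TestUnionCandidates:
    def _sr(self, t1, t2, measure="pearson"):
        return ScreenResult(np.zeros(10), t1, t2, measure)

    def test_overlap_ratio(self):
        C, overlap = union_candidates(self._sr([1], [2]),
                                      self._sr([2], [3], "mutual_information"))
        assert list(C) == [1, 2, 3]
        assert overlap == pytest.approx(1 / 3)

    def test_disjoint_sets_concatenate(self):
        C, overlap = union_candidates(self._sr([1, 2], []),
                                      self._sr([5], [7], "mutual_information"))
        assert list(C) == [1, 2, 5, 7] and overlap == 0.0

    def test_identical_sets(self):
        C, overlap = union_candidates(self._sr([1, 2], []),
                                      self._sr([1, 2], [], "mutual_information"))
        assert list(C) == [1, 2] and overlap == 1.0


def test_screen_sets_disjoint_on_simulated_panel(small_panel):
    G, y, _, _ = small_panel
    for measure in ("pearson", "mi"):
        res = screen(G.X, y, measure)
        assert not set(res.type_i) & set(res.type_ii)
        assert res.size == res.type_i.size + res.type_ii.size


def test_null_panel_candidate_count_stays_small(rng):
    """On SNPs independent of the trait the mean candidate-set size over
    seeded replicates stays well below n."""
    sizes = []
    for rep in range(10):
        G = sim.simulate_genotypes(80, 400, seed=900 + rep)
        y = PhenotypeVector(np.random.default_rng(rep).normal(size=80))
        A = screen(G.X.astype(float), y, "pearson")
        B = screen(G.X.astype(float), y, "mi")
        C, _ = union_candidates(A, B)
        sizes.append(C.size)
    assert np.mean(sizes) < 80 / 2
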