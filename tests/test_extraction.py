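import numpy as np
import pytest

import motormod as mm
from motormod.extraction import vaf_curve


class TestComputeVaf:
    def test_perfect_reconstruction(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert mm.compute_vaf(E, E) == 1.0

    def test_zero_reconstruction(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert mm.compute_vaf(E, np.zeros_like(E)) == 0.0

    def test_hand_computed_value(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        E_hat = np.array([[1.0, 1.0], [3.0, 3.0]])
        assert mm.compute_vaf(E, E_hat) == pytest.approx(1 - 2 / 30)

    def test_worse_than_zero_reconstruction_is_negative(self):
        E = np.array([[1.0, 1.0]])
        assert mm.compute_vaf(E, 3 * E) < 0

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            mm.compute_vaf(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.compute_vaf(np.ones((2, 2)), np.ones((2, 3)))


class TestNmfDecompose:
    def test_rank_one_factorizes_exactly(self):
        rng = np.random.default_rng(0)
        E = np.outer(rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 40))
        res = mm.nmf_decompose(E, 1, seed=0, replicates=5)
        assert res.vaf >= 0.999

    def test_zero_muscle_row_yields_zero_weight_row(self):
        rng = np.random.default_rng(1)
        E = rng.uniform(0, 1, size=(5, 30))
        E[2] = 0.0
        res = mm.nmf_decompose(E, 2, seed=0, replicates=3)
        assert np.all(np.abs(res.W[2]) <= 1e-9)

    def test_factors_nonnegative_and_columns_unit_max(self, ref_extraction):
        assert np.all(ref_extraction.W >= 0)
        assert np.all(ref_extraction.C >= 0)
        np.testing.assert_allclose(ref_extraction.W.max(axis=0), 1.0)

    def test_objective_nonincreasing_per_iteration(self, ref_extraction):
        h = ref_extraction.objective_history
        assert np.all(np.diff(h) <= 1e-9 * np.maximum(h[:-1], 1.0))

    def test_rescaling_leaves_reconstruction_unchanged(self, ref_E):
        """Unit-max column scaling of W is compensated in C: W@C invariant."""
        from motormod.extraction import _mu_nmf, _normalize_columns

        rng = np.random.default_rng(3)
        W, C, _, _ = _mu_nmf(np.asarray(ref_E, float), 3, rng, 500, 1e-8)
        Wn, Cn = _normalize_columns(W, C)
        np.testing.assert_allclose(Wn @ Cn, W @ C, atol=1e-12)
        np.testing.assert_allclose(Wn.max(axis=0), 1.0)

    def test_planted_modules_recovered_at_default_noise(
        self, subset_truth, ref_E
    ):
        res = mm.nmf_decompose(ref_E, 3, seed=0, replicates=10)
        pairing = mm.match_modules(subset_truth.W_true, res.W)
        assert np.all(pairing.r_values >= 0.9)

    def test_matches_sklearn_mu_solver_vaf(self, ref_E):
        """Independent NMF implementation reaches the same VAF plateau."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        ours = mm.nmf_decompose(ref_E, 3, seed=0, replicates=10)
        best_ref = -np.inf
        for rs in range(5):
            model = sklearn.NMF(
                n_components=3,
                solver="mu",
                beta_loss="frobenius",
                init="random",
                max_iter=2000,
                tol=1e-6,
                random_state=rs,
            )
            W = model.fit_transform(np.asarray(ref_E))
            best_ref = max(best_ref, mm.compute_vaf(ref_E, W @ model.components_))
        assert ours.vaf == pytest.approx(best_ref, abs=2e-3)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            mm.nmf_decompose(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_excessive_module_count_rejected(self):
        with pytest.raises(ValueError):
            mm.nmf_decompose(np.ones((3, 10)), 4)

    def test_deterministic_given_seed(self, ref_E):
        a = mm.nmf_decompose(ref_E, 3, seed=7, replicates=3)
        b = mm.nmf_decompose(ref_E, 3, seed=7, replicates=3)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.C, b.C)


class TestSelectModuleNumber:
    def test_rank_one_data_selects_one_module(self):
        rng = np.random.default_rng(2)
        E = np.outer(rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 40))
        n, curve = mm.select_module_number(E, 0.95, n_max=4, replicates=3, seed=0)
        assert n == 1

    def test_planted_three_module_data_selects_three(self, ref_E):
        n, _ = mm.select_module_number(ref_E, 0.95, n_max=8, replicates=10, seed=0)
        assert n == 3

    def test_vaf_curve_nondecreasing(self, ref_vaf_curve):
        assert np.all(np.diff(ref_vaf_curve.vaf_at_n) >= -1e-3)

    def test_selection_monotone_in_threshold(self, ref_vaf_curve):
        n90 = ref_vaf_curve.smallest_n_above(0.90)
        n95 = ref_vaf_curve.smallest_n_above(0.95)
        assert n90 <= n95

    def test_unreachable_threshold_warns_and_returns_n_max(self):
        rng = np.random.default_rng(4)
        E = rng.uniform(0.1, 1.0, size=(6, 50))  # full-rank noise
        with pytest.warns(RuntimeWarning):
            n, curve = mm.select_module_number(
                E, 0.999999, n_max=2, replicates=2, seed=0
            )
        assert n == 2
        assert not curve.threshold_reached

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            mm.select_module_number(np.ones((3, 5)), threshold=1.5)
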