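import numpy as np
import pytest

import motormod as mm
from motormod.muscles import MODULE_ROLES_FULL, MODULE_ROLES_SUBSET
from motormod.synthetic import ModulationGains, make_activation_patterns


class TestModuleTemplates:
    def test_plantarflexor_module_dominated_by_soleus_and_gastroc(self):
        W = mm.make_module_templates(mm.SUBSET_8, 3)
        j = MODULE_ROLES_SUBSET.index("plantarflexor")
        order = np.argsort(W[:, j])[::-1]
        top2 = {mm.SUBSET_8.names[i] for i in order[:2]}
        assert top2 == {"SOL", "GM"}

    def test_columns_nonnegative_unit_max(self):
        W = mm.make_module_templates(mm.SUBSET_8, 3)
        assert np.all(W >= 0)
        np.testing.assert_allclose(W.max(axis=0), 1.0)

    def test_full_set_shape(self):
        W = mm.make_module_templates(mm.FULL_43, 4)
        assert W.shape == (43, 4)

    def test_dorsiflexor_module_dominated_by_tibialis_anterior(self):
        W = mm.make_module_templates(mm.FULL_43, 4)
        j = MODULE_ROLES_FULL.index("dorsiflexor")
        assert mm.FULL_43.names[int(np.argmax(W[:, j]))] == "TA"

    def test_four_modules_rejected_for_subset(self):
        with pytest.raises(ValueError):
            mm.make_module_templates(mm.SUBSET_8, 4)

    def test_unknown_muscle_label_is_configuration_error(self):
        from motormod.muscles import MuscleSetDefinition

        bad = MuscleSetDefinition(
            name="bad",
            names=("A", "B", "C"),
            module_roles=("stance_extensor", "plantarflexor", "dorsiflexor"),
            module_template_map={
                "stance_extensor": {"A": 1.0},
                "plantarflexor": {"NOPE": 1.0},
                "dorsiflexor": {"C": 1.0},
            },
        )
        with pytest.raises(KeyError):
            mm.make_module_templates(bad, 3)


class TestActivationPatterns:
    def test_plantarflexor_bump_peaks_in_late_stance(self):
        ref = mm.reference_condition("right", "full_43")
        C = make_activation_patterns(ref, 4)
        j = MODULE_ROLES_FULL.index("plantarflexor")
        peak_idx = int(np.argmax(C[j]))
        # late stance: second half of the ~60% stance phase
        assert 30 <= peak_idx <= 60

    def test_zero_gains_make_patterns_condition_invariant(self):
        gains = ModulationGains.zero()
        ref = mm.reference_condition("right", "full_43")
        C_ref = make_activation_patterns(ref, 4, gains=gains)
        for cond in mm.condition_grid("right", "full_43"):
            C = make_activation_patterns(cond, 4, gains=gains)
            np.testing.assert_array_equal(C, C_ref)

    def test_plantarflexor_peak_increases_with_speed(self):
        slow = mm.ConditionSpec(0.8, 0.0, 0.1, "right", "full_43")
        fast = mm.ConditionSpec(1.45, 0.0, 0.1, "right", "full_43")
        j = MODULE_ROLES_FULL.index("plantarflexor")
        C_slow = make_activation_patterns(slow, 4)
        C_fast = make_activation_patterns(fast, 4)
        assert C_fast[j].max() > C_slow[j].max()

    def test_hip_flexor_peak_increases_with_asymmetry(self):
        sym = mm.ConditionSpec(1.1, 0.0, 0.1, "right", "full_43")
        asym = mm.ConditionSpec(1.1, 0.30, 0.1, "right", "full_43")
        j = MODULE_ROLES_FULL.index("hip_flexor")
        assert (
            make_activation_patterns(asym, 4)[j].max()
            > make_activation_patterns(sym, 4)[j].max()
        )

    def test_wide_steps_add_swing_activity_to_extensor_module(self):
        narrow = mm.ConditionSpec(1.1, 0.0, 0.1, "right", "full_43")
        wide = mm.ConditionSpec(1.1, 0.0, 0.3, "right", "full_43")
        j = MODULE_ROLES_FULL.index("stance_extensor")
        swing = slice(65, 90)
        assert (
            make_activation_patterns(wide, 4)[j][swing].sum()
            > make_activation_patterns(narrow, 4)[j][swing].sum()
        )

    def test_nonnegative_and_shape(self):
        for cond in mm.condition_grid("left", "full_43"):
            C = make_activation_patterns(cond, 4)
            assert C.shape == (4, 101)
            assert np.all(C >= 0)

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ValueError):
            make_activation_patterns(mm.reference_condition(), 3, T=2)


class TestSynthesizeActivations:
    def test_zero_noise_is_exact_product(self, subset_truth_noiseless, ref_condition):
        E = mm.synthesize_activations(subset_truth_noiseless, ref_condition)
        expected = subset_truth_noiseless.W_true @ subset_truth_noiseless.C_true(
            ref_condition
        )
        np.testing.assert_array_equal(E, expected)

    def test_same_seed_bit_identical(self, subset_truth, ref_condition):
        E1 = mm.synthesize_activations(subset_truth, ref_condition)
        E2 = mm.synthesize_activations(subset_truth, ref_condition)
        np.testing.assert_array_equal(E1, E2)

    def test_nonnegative_with_correct_shape_everywhere(self, subset_truth):
        for leg in ("left", "right"):
            for cond in mm.condition_grid(leg):
                E = mm.synthesize_activations(subset_truth, cond)
                assert E.shape == (8, 101)
                assert np.all(E >= 0)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            mm.make_ground_truth(mm.SUBSET_8, noise_sd=-0.1)

    def test_zero_noise_factorization_is_exact(
        self, subset_truth_noiseless, ref_condition
    ):
        """An exact rank-3 factorization exists by construction."""
        E = mm.synthesize_activations(subset_truth_noiseless, ref_condition)
        res = mm.nmf_decompose(E, 3, seed=0, replicates=10)
        assert res.vaf >= 0.999


class TestParameterRecovery:
    def test_noiseless_extraction_recovers_planted_modules(
        self, subset_truth_noiseless, ref_condition
    ):
        E = mm.synthesize_activations(subset_truth_noiseless, ref_condition)
        res = mm.nmf_decompose(E, 3, seed=0, replicates=10)
        pairing = mm.match_modules(subset_truth_noiseless.W_true, res.W)
        assert np.all(pairing.r_values >= 0.95)

    def test_bilateral_similarity_of_symmetric_gait(self, subset_truth):
        sym_left = mm.ConditionSpec(1.1, 0.0, 0.1, "left")
        sym_right = mm.ConditionSpec(1.1, 0.0, 0.1, "right")
        E_l = mm.synthesize_activations(subset_truth, sym_left)
        E_r = mm.synthesize_activations(subset_truth, sym_right)
        W_l = mm.nmf_decompose(E_l, 3, seed=0, replicates=10).W
        W_r = mm.nmf_decompose(E_r, 3, seed=1, replicates=10).W
        bil = mm.bilateral_similarity(W_l, W_r)
        assert bil.mean_r >= 0.95
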