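"""Gcn2-gated population layer: gating map, presets, induction, regrowth."""

import math

import numpy as np
import pytest
from scipy import stats

from gcn4set import (
    Gcn2Model,
    apply_mutant_preset,
    gcn2_overexpression,
    induction_timecourse,
    lambda_of_gcn2,
    regrowth_simulation,
    sample_gcn2_activity,
    sample_population,
)
from gcn4set.population_model import PRESET_NAMES


class TestGcn2Activity:
    def test_threshold_matches_exceedance(self):
        model = Gcn2Model(exceed_prob=0.03)
        G = sample_gcn2_activity(model, 100_000, seed=1)
        frac = np.mean(G > model.threshold)
        se = math.sqrt(0.03 * 0.97 / G.size)
        assert abs(frac - 0.03) < 3 * se

    def test_vanishing_spread_is_degenerate(self):
        model = Gcn2Model(sigma_g=1e-9)
        G = sample_gcn2_activity(model, 1000, seed=2)
        assert np.allclose(G, math.exp(model.mu_g))
        # any threshold away from the atom gives an all-or-nothing split
        assert np.mean(G > 1.1 * math.exp(model.mu_g)) == 0.0
        assert np.mean(G > 0.9 * math.exp(model.mu_g)) == 1.0

    def test_sample_reproducible_and_validated(self):
        model = Gcn2Model()
        assert np.array_equal(sample_gcn2_activity(model, 100, seed=3),
                              sample_gcn2_activity(model, 100, seed=3))
        with pytest.raises(ValueError):
            sample_gcn2_activity(model, 0, seed=0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            Gcn2Model(tau_g=0.0)
        with pytest.raises(ValueError):
            Gcn2Model(exceed_prob=1.5)
        with pytest.raises(ValueError):
            Gcn2Model(lambda_derepressed=0.6)  # above the ceiling


class TestLambdaGating:
    def test_threshold_boundary_stays_repressed(self):
        model = Gcn2Model()
        assert lambda_of_gcn2(model.threshold, model) == 0.54

    def test_high_activity_derepresses(self):
        model = Gcn2Model()
        assert lambda_of_gcn2(10 * model.threshold, model) == 0.33

    def test_low_activity_capped_at_repressed_ceiling(self):
        model = Gcn2Model()
        assert lambda_of_gcn2(1e-6, model) == 0.54

    def test_graded_variant_monotone_and_capped(self):
        model = Gcn2Model(graded=True)
        G = np.geomspace(model.threshold / 100, model.threshold * 100, 200)
        lam = lambda_of_gcn2(G, model)
        assert np.all(np.diff(lam) <= 1e-12)
        assert lam.max() <= 0.54
        assert lam.min() == pytest.approx(0.33)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            lambda_of_gcn2(0.0, Gcn2Model())


class TestPresets:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError) as err:
            apply_mutant_preset("gcn3_delta")
        for name in PRESET_NAMES:
            assert name in str(err.value)

    def test_wild_type_roundtrips_defaults(self):
        bundle = apply_mutant_preset("wild_type")
        assert bundle.scan.lam == 0.54
        assert bundle.mode == "normal"
        assert not bundle.lambda_pinned

    def test_gcn2_delta_pins_lambda(self):
        pop = sample_population("gcn2_delta", 5000, seed=4)
        assert np.all(pop["lambda"] == 0.54)
        assert pop["set_truth"].sum() == 0

    def test_no_uorf_control_flux_is_upper_bound(self):
        pop = sample_population("no_uorf_control", 1000, seed=5)
        bundle = apply_mutant_preset("no_uorf_control")
        assert np.all(pop["flux"] == bundle.scan.alpha)
        wt = sample_population("wild_type", 1000, seed=5)
        assert pop["flux"].min() >= wt["flux"].max()


class TestPopulationSampling:
    def test_truth_fraction_matches_exceedance(self):
        pop = sample_population("wild_type", 100_000, seed=6)
        se = math.sqrt(0.03 * 0.97 / len(pop))
        assert abs(pop["set_truth"].mean() - 0.03) < 3 * se

    def test_lambda_never_exceeds_repressed_ceiling(self):
        for preset in PRESET_NAMES:
            pop = sample_population(preset, 2000, seed=7)
            assert pop["lambda"].max() <= 0.54

    def test_wild_type_modes_well_separated(self):
        pop = sample_population("wild_type", 50_000, seed=8)
        hi = pop.loc[pop.set_truth, "fluorescence"].mean()
        lo = pop.loc[~pop.set_truth, "fluorescence"].mean()
        assert hi / lo > 5.0

    def test_uorf1_ata_collapses_separation(self):
        pop = sample_population("uorf1_ata", 50_000, seed=9)
        hi = pop.loc[pop.set_truth, "fluorescence"].mean()
        lo = pop.loc[~pop.set_truth, "fluorescence"].mean()
        assert hi / lo < 1.5

    def test_reproducible(self):
        a = sample_population("wild_type", 500, seed=10)
        b = sample_population("wild_type", 500, seed=10)
        assert a.equals(b)


class TestInduction:
    def test_zero_drift_is_stationary(self):
        tc = induction_timecourse("wild_type", [0, 2, 4], drift=0.0,
                                  n_cells=20_000, seed=11)
        fracs = [t["set_truth"].mean() for t in tc.values()]
        se = math.sqrt(0.03 * 0.97 / 20_000)
        assert max(fracs) - min(fracs) < 6 * se

    def test_default_drift_transitions_population(self):
        tc = induction_timecourse("wild_type", [0, 1, 2, 3, 4],
                                  n_cells=20_000, seed=12)
        means = [t["fluorescence"].mean() for t in tc.values()]
        assert np.all(np.diff(means) > 0)
        assert list(tc.values())[-1]["set_truth"].mean() > 0.99

    def test_s51a_does_not_transition(self):
        tc = induction_timecourse("eif2a_s51a", [0, 4], n_cells=10_000,
                                  seed=13)
        m0, m4 = [t["fluorescence"].mean() for t in tc.values()]
        assert abs(m4 / m0 - 1.0) < 0.05

    def test_negative_drift_rejected(self):
        with pytest.raises(ValueError):
            induction_timecourse("wild_type", [0, 1], drift=-0.5)

    def test_unsorted_hours_rejected(self):
        with pytest.raises(ValueError):
            induction_timecourse("wild_type", [2, 1])


class TestOverexpression:
    def test_single_copy_reduces_to_wild_type(self):
        pop = gcn2_overexpression({1: 1.0}, 50_000, seed=14)
        se = math.sqrt(0.03 * 0.97 / len(pop))
        assert abs(pop["set_truth"].mean() - 0.03) < 3 * se

    def test_copy_number_variation_enlarges_set_fraction(self):
        pop = gcn2_overexpression({k: 0.2 for k in range(1, 6)}, 100_000,
                                  seed=15)
        assert pop["set_truth"].mean() > 0.03

    def test_reproducible_and_validated(self):
        a = gcn2_overexpression({1: 0.5, 3: 0.5}, 300, seed=16)
        b = gcn2_overexpression({1: 0.5, 3: 0.5}, 300, seed=16)
        assert a.equals(b)
        with pytest.raises(ValueError):
            gcn2_overexpression({0: 1.0}, 100, seed=0)
        with pytest.raises(ValueError):
            gcn2_overexpression({1: 0.4, 2: 0.4}, 100, seed=0)


class TestRegrowth:
    def test_frozen_process_keeps_sorted_state(self):
        fr = regrowth_simulation("set", 5, Gcn2Model(tau_g=1e12), seed=17)
        assert fr[0] == 1.0
        assert np.all(fr > 0.99)

    def test_sorted_set_cells_relax_within_ten_generations(self):
        fr = regrowth_simulation("set", 12, Gcn2Model(), seed=18,
                                 n_cells=20_000)
        assert fr[0] == 1.0
        assert abs(fr[10] - 0.03) <= 0.1 * 0.03 + 3 * math.sqrt(
            0.03 * 0.97 / 20_000)

    def test_non_set_start_relaxes_upward(self):
        fr = regrowth_simulation("non_set", 12, Gcn2Model(), seed=19,
                                 n_cells=20_000)
        assert fr[0] == 0.0
        assert fr[10] == pytest.approx(0.03, abs=0.01)

    def test_activity_marginal_reaches_stationary_lognormal(self):
        model = Gcn2Model()
        fr, G = regrowth_simulation("set", 12, model, seed=20,
                                    n_cells=10_000, return_state=True)
        z = (np.log(G) - model.mu_g) / model.sigma_g
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            regrowth_simulation("set", 0, Gcn2Model(), seed=0)
        with pytest.raises(ValueError):
            regrowth_simulation("sideways", 3, Gcn2Model(), seed=0)
        with pytest.raises(ValueError):
            regrowth_simulation(np.array([-1.0, 2.0]), 3, Gcn2Model(),
                                seed=0)
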