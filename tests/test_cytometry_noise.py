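"""Cytometry processing: trimming, gates, CV curves, noise, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcn4set import (
    GateSpec,
    classify_set,
    cv_curve,
    density_centre,
    dual_reporter_noise,
    fit_population_distributions,
    radial_gate,
    rectangular_gate,
    trim_events,
)


def _events(n, rng, fsc=59_000.0, ssc=27_000.0, fsc_sd=3000.0,
            ssc_sd=3000.0, duration=10.0):
    return pd.DataFrame({
        "time": np.sort(rng.uniform(0, duration, n)),
        "fsc": rng.normal(fsc, fsc_sd, n),
        "ssc": rng.normal(ssc, ssc_sd, n),
        "fl1": rng.normal(1000.0, 100.0, n),
    })


class TestTrim:
    def test_uniform_acquisition_loses_expected_fraction(self, rng):
        ev = _events(20_000, rng)
        kept = trim_events(ev)
        span = ev.time.max() - ev.time.min()
        expected = 1.0 - 1.2 / span
        frac = len(kept) / len(ev)
        se = math.sqrt(expected * (1 - expected) / len(ev))
        assert abs(frac - expected) < 3 * se

    def test_zero_margins_are_identity(self, rng):
        ev = _events(500, rng)
        assert trim_events(ev, head=0.0, tail=0.0).equals(ev)

    def test_already_trimmed_unchanged(self, rng):
        ev = _events(500, rng)
        ev["time"] = np.linspace(1.0, 10.0 - 0.2, 500)
        out = trim_events(pd.concat([
            pd.DataFrame({"time": [0.0], "fsc": [0.0], "ssc": [0.0],
                          "fl1": [0.0]}),
            ev,
            pd.DataFrame({"time": [10.0], "fsc": [0.0], "ssc": [0.0],
                          "fl1": [0.0]})]))
        assert out.reset_index(drop=True).equals(ev)

    def test_empty_result_warns(self, rng):
        ev = _events(50, rng, duration=0.5)
        with pytest.warns(UserWarning):
            trim_events(ev)


class TestRectangularGate:
    def test_boundaries_inclusive(self):
        ev = pd.DataFrame({"time": [0, 0, 0], "fl1": [1, 1, 1],
                           "fsc": [40_000.0, 39_999.0, 100_000.0],
                           "ssc": [50_000.0, 50_000.0, 50_000.0]})
        kept = rectangular_gate(ev)
        assert kept["fsc"].tolist() == [40_000.0, 100_000.0]

    def test_known_in_gate_fraction(self, rng):
        n = 50_000
        ev = pd.DataFrame({
            "time": np.zeros(n), "fl1": np.ones(n),
            "fsc": rng.uniform(0, 200_000, n),
            "ssc": rng.uniform(0, 180_000, n),
        })
        p = (60_000 / 200_000) * (80_000 / 180_000)
        frac = len(rectangular_gate(ev)) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se


class TestDensityCentre:
    def test_tight_gaussian_cluster_mode_is_mean(self, rng):
        ev = _events(30_000, rng, fsc_sd=800.0, ssc_sd=800.0)
        fc, sc = density_centre(ev)
        assert fc == pytest.approx(59_000, rel=0.02)
        assert sc == pytest.approx(27_000, rel=0.02)

    def test_manual_centre_bypasses_estimation(self, rng):
        ev = _events(200, rng)
        spec = GateSpec(centre=(59_000.0, 27_000.0))
        assert density_centre(ev, spec) == (59_000.0, 27_000.0)

    def test_centre_lands_in_denser_cluster(self, rng):
        a = _events(20_000, rng, fsc=50_000, ssc=20_000, fsc_sd=1500,
                    ssc_sd=1500)
        b = _events(2_000, rng, fsc=80_000, ssc=60_000, fsc_sd=1500,
                    ssc_sd=1500)
        fc, sc = density_centre(pd.concat([a, b], ignore_index=True))
        assert abs(fc - 50_000) < 5_000
        assert abs(sc - 20_000) < 5_000

    def test_too_few_events(self, rng):
        with pytest.raises(ValueError):
            density_centre(_events(50, rng))


class TestRadialGate:
    def test_centre_event_always_kept(self):
        ev = pd.DataFrame({"time": [0.0], "fsc": [59_000.0],
                           "ssc": [27_000.0], "fl1": [1.0]})
        assert len(radial_gate(ev, (59_000, 27_000), 1e-9)) == 1

    def test_boundary_inclusive(self):
        ev = pd.DataFrame({"time": [0.0], "fsc": [59_300.0],
                           "ssc": [27_400.0], "fl1": [1.0]})
        assert len(radial_gate(ev, (59_000, 27_000), 500.0)) == 1
        assert len(radial_gate(ev, (59_000, 27_000), 499.0)) == 0

    def test_uniform_disc_area_fraction(self, rng):
        n = 50_000
        r = np.sqrt(rng.uniform(0, 1, n)) * 10_000
        th = rng.uniform(0, 2 * np.pi, n)
        ev = pd.DataFrame({"time": np.zeros(n), "fl1": np.ones(n),
                           "fsc": 59_000 + r * np.cos(th),
                           "ssc": 27_000 + r * np.sin(th)})
        frac = len(radial_gate(ev, (59_000, 27_000), 5_000)) / n
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se


class TestCvCurve:
    radii = [1000, 2000, 4000, 8000]

    def test_constant_channel_has_zero_cv(self, rng):
        ev = _events(10_000, rng)
        ev["fl1"] = 500.0
        curve = cv_curve(ev, self.radii)
        assert np.allclose(curve["cv_percent"], 0.0)

    def test_size_independent_channel_is_flat(self, rng):
        ev = _events(50_000, rng)  # fl1 independent of scatter
        curve = cv_curve(ev, self.radii)
        cv = curve["cv_percent"].to_numpy()
        assert np.nanmax(cv) - np.nanmin(cv) < 0.1 * np.nanmean(cv)

    def test_size_coupled_channel_narrows_with_radius(self, rng):
        n = 60_000
        size = np.exp(rng.normal(0, 0.2, n))
        ev = pd.DataFrame({
            "time": np.zeros(n),
            "fsc": 59_000 * size * np.exp(rng.normal(0, 0.05, n)),
            "ssc": 27_000 * size * np.exp(rng.normal(0, 0.05, n)),
            "fl1": 1000 * size * np.exp(rng.normal(0, 0.05, n)),
        })
        curve = cv_curve(ev, [1000, 2000, 4000, 8000, 16000, 32000])
        good = curve[~curve["flagged"]]
        assert good["cv_percent"].iloc[0] < good["cv_percent"].iloc[-1]

    def test_thin_radii_flagged_not_dropped(self, rng):
        ev = _events(2_000, rng)
        curve = cv_curve(ev, [10, 8000])
        assert len(curve) == 2
        assert bool(curve["flagged"].iloc[0])
        assert not bool(curve["flagged"].iloc[1])


class TestDualReporterNoise:
    def test_identical_channels_have_no_intrinsic_noise(self, rng):
        g = rng.lognormal(7, 0.3, 10_000)
        ev = pd.DataFrame({"fl1": g, "fl2": g})
        d = dual_reporter_noise(ev)
        assert d.eta_int_sq == pytest.approx(0.0, abs=1e-12)
        assert d.eta_tot_sq == pytest.approx(d.eta_ext_sq, abs=1e-12)

    def test_proportional_channels_have_no_intrinsic_noise(self, rng):
        g = rng.lognormal(7, 0.3, 10_000)
        ev = pd.DataFrame({"fl1": g, "fl2": 3.7 * g})
        d = dual_reporter_noise(ev)
        assert d.eta_int_sq == pytest.approx(0.0, abs=1e-12)

    def test_independent_channels_are_all_intrinsic(self, rng):
        c = 0.2
        sig = math.sqrt(math.log(1 + c**2))
        n = 100_000
        ev = pd.DataFrame({
            "fl1": np.exp(rng.normal(-sig**2 / 2, sig, n)),
            "fl2": np.exp(rng.normal(-sig**2 / 2, sig, n)),
        })
        d = dual_reporter_noise(ev)
        assert d.eta_ext_sq == pytest.approx(0.0, abs=0.005)
        assert d.eta_int_sq == pytest.approx(c**2, rel=0.1)

    def test_zero_mean_rejected(self):
        ev = pd.DataFrame({"fl1": [0.0, 0.0], "fl2": [1.0, 1.0]})
        with pytest.raises(ValueError):
            dual_reporter_noise(ev)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_decomposition_identity_on_arbitrary_inputs(self, seed):
        r = np.random.default_rng(seed)
        ev = pd.DataFrame({"fl1": r.gamma(2.0, 50.0, 300) + 1.0,
                           "fl2": r.lognormal(4.0, 0.5, 300) + 1.0})
        d = dual_reporter_noise(ev)
        assert d.eta_int_sq + d.eta_ext_sq == pytest.approx(
            d.eta_tot_sq, abs=1e-12)


class TestClassifySet:
    def test_percentile_flags_exact_fraction(self, rng):
        values = rng.normal(1000, 100, 10_000)
        labels, frac = classify_set(values, q=97)
        assert frac == pytest.approx(0.03, abs=1e-9)
        assert labels.sum() == 300
        # flagged cells are exactly the top of the ranking
        assert values[labels].min() >= values[~labels].max()

    def test_percentile_out_of_range(self, rng):
        with pytest.raises(ValueError):
            classify_set(rng.normal(1000, 100, 1000), q=30)

    def test_model_based_on_unimodal_data_flags_almost_nothing(self, rng):
        values = rng.normal(1000, 100, 100_000)
        _, frac = classify_set(values, method="model_based")
        assert frac <= 0.005

    def test_model_based_recovers_separated_subpopulation(
            self, wild_type_events):
        labels, frac = classify_set(wild_type_events, method="model_based")
        truth = wild_type_events["set_truth"].to_numpy()
        recall = labels[truth].mean()
        assert recall >= 0.9
        assert frac == pytest.approx(truth.mean(), abs=0.01)

    def test_model_based_needs_enough_events(self, rng):
        with pytest.raises(ValueError):
            classify_set(rng.normal(1000, 100, 500), method="model_based")


class TestDistributionFits:
    def test_pure_normal_sample_prefers_normal(self, rng):
        x = rng.normal(3.0, 0.1, 10_000)
        fits = fit_population_distributions(x, seed=0)
        best = fits[0]
        normal = next(f for f in fits if f.model == "normal")
        assert normal.bic - best.bic <= 2.0

    def test_mixture_recovers_minor_weight(self, rng):
        x = np.concatenate([rng.normal(3.0, 0.1, 9_700),
                            rng.normal(4.0, 0.1, 300)])
        fits = fit_population_distributions(x, seed=0)
        assert fits[0].model == "two_component_mixture"
        assert min(fits[0].weights) == pytest.approx(0.03, abs=0.01)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_population_distributions(np.full(1000, 2.0))

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_population_distributions(rng.normal(0, 1, 100))


class TestGateAlgebra:
    def test_gates_idempotent(self, rng):
        ev = _events(5_000, rng)
        once = rectangular_gate(ev)
        assert rectangular_gate(once).equals(once)
        r_once = radial_gate(ev, (59_000, 27_000), 5_000)
        assert radial_gate(r_once, (59_000, 27_000), 5_000).equals(r_once)

    def test_nested_gates_commute(self, rng):
        ev = _events(5_000, rng)
        a = radial_gate(rectangular_gate(ev), (59_000, 27_000), 5_000)
        b = rectangular_gate(radial_gate(ev, (59_000, 27_000), 5_000))
        assert a.equals(b)
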