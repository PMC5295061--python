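import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import avkinetics as av
from avkinetics.errors import AlignmentError, ConfigError, InfeasibleTruthError
from avkinetics.kinetics import FLUX_FIELDS, TRACER_FLUX_FIELDS
from avkinetics.simulate import _default_pah_infusion


def _no_exchange_truth():
    return av.SimTruth(
        plasma_flow=1.3,
        c_art={"leucine": 130.0, "kic": 45.0, "co2": 18000.0, "pah": 8.0},
        e_art={"leucine": 0.05, "kic": 0.015, "co2": 3e-4},
        c_ven_co2=18000.0, net_uptake=0.0, utilization=0.0,
        net_transamination=0.0, oxidation=0.0, kic13_production=0.0)


class TestInversion:
    def test_no_exchange_means_identical_sides(self):
        truth = _no_exchange_truth()
        venous = av.invert_truth_to_venous(truth)
        for analyte in ("leucine", "kic", "co2"):
            c_v, e_v = venous[analyte]
            assert c_v == pytest.approx(truth.c_art[analyte])
            assert e_v == pytest.approx(truth.e_art[analyte])

    def test_complete_extraction_boundary(self, control):
        truth = replace(control,
                        utilization=control.plasma_flow
                        * control.c_art["leucine"])
        assert av.invert_truth_to_venous(truth)["leucine"][1] == \
            pytest.approx(0.0, abs=1e-15)

    def test_infeasible_uptake_rejected(self, control):
        bad = replace(control, net_uptake=10 * control.plasma_flow
                      * control.c_art["leucine"])
        with pytest.raises(InfeasibleTruthError):
            av.invert_truth_to_venous(bad)

    def test_indicator_dilution_consistent(self, control):
        pah_inf = _default_pah_infusion()
        c_v = av.invert_truth_to_venous(control)["pah"][0]
        assert pah_inf / (c_v - control.c_art["pah"]) / control.body_weight \
            == pytest.approx(control.plasma_flow, rel=1e-12)


class TestSimulateAnimal:
    def test_same_seed_identical_tables(self, control):
        a = av.simulate_animal(control, rng=123, noise=av.NoiseModel())
        b = av.simulate_animal(control, rng=123, noise=av.NoiseModel())
        assert a.to_csv() == b.to_csv()  # byte-identical

    def test_plateau_reached_within_exponential_bound(self, control):
        # rise constant 4/h sampled 5-8 h after the phase start: the last-3
        # window mean sits within 1e-6 (relative) of the plateau
        slow = replace(control, k_rise={"leucine": 4.0, "kic": 4.0,
                                        "co2": 12.0, "pah": 30.0})
        df = av.simulate_animal(slow, times=np.arange(0.0, 11.0), noise=None)
        sub = df[(df.analyte == "leucine") & (df.site == "artery")]
        w = av.last_k_plateau(sub["time_h"],
                              sub["enrichment_mpe"].astype(float), 3)
        assert w.mean == pytest.approx(100 * control.e_art["leucine"],
                                       rel=1e-6)

    def test_pre_phase_samples_sit_at_baseline(self, control):
        df = av.simulate_animal(control, noise=None)
        leu0 = df[(df.analyte == "leucine") & (df.site == "artery")
                  & (df.time_h == 0.0)]
        assert leu0["enrichment_mpe"].iloc[0] == 0.0
        assert leu0["concentration"].iloc[0] == pytest.approx(
            0.85 * control.c_art["leucine"])

    def test_negative_times_warn(self, control):
        with pytest.warns(UserWarning, match="baseline"):
            av.simulate_animal(control, times=[-1.0, 0.0, 6.0, 7.0, 8.0],
                               noise=None)


class TestForwardInverse:
    def test_identity_on_random_truths(self):
        """analyze(simulate(truth, noise=0)) == truth, property-sampled."""
        rng = np.random.default_rng(17)
        from avkinetics.hemodynamics import (default_protocols,
                                             pah_infusion_mg_per_h,
                                             plasma_flow_pah)
        from avkinetics.plateau import animal_steady_states
        pah_mg = pah_infusion_mg_per_h(default_protocols()["pah"])
        for _ in range(25):
            truth = av.random_truth(rng)
            df = av.normalize_units(av.validate_samples(
                av.simulate_animal(truth, noise=None)))
            ss = animal_steady_states(df)
            pf = plasma_flow_pah(pah_mg,
                                 ss[("pah", "artery")].mean_concentration,
                                 ss[("pah", "vein")].mean_concentration,
                                 truth.body_weight)
            panel = av.analyze_animal(ss, pf)
            for flux, v in av.true_fluxes(truth).items():
                if flux == "plasma_flow":
                    assert pf.value == pytest.approx(v, rel=1e-9)
                else:
                    assert getattr(panel, flux) == pytest.approx(
                        v, rel=1e-9), flux


class TestCohort:
    def test_single_animal_groups_rejected(self):
        with pytest.raises(ConfigError):
            av.SimCohortConfig(n_per_group=1)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ConfigError):
            av.SimCohortConfig(times=(0.0, 2.0, 1.0))

    def test_seed_determinism(self):
        a = av.simulate_cohort(av.SimCohortConfig(seed=9))
        b = av.simulate_cohort(av.SimCohortConfig(seed=9))
        assert a.samples.to_csv() == b.samples.to_csv()
        assert not a.samples.equals(
            av.simulate_cohort(av.SimCohortConfig(seed=10)).samples)

    def test_zero_noise_group_means_equal_truth(self, clean_cohort):
        res = av.analyze_cohort(clean_cohort.samples)
        rep = av.recovery_report(clean_cohort.truth_table, res.kinetics)
        assert rep["relative_bias_percent"].abs().max() < 1e-7

    def test_between_animal_spread_present(self, noisy_cohort):
        flows = noisy_cohort.truth_table.groupby("group")["plasma_flow"]
        assert (flows.std() > 0).all()


class TestRecoveryReport:
    def test_perfect_estimates(self, clean_cohort):
        rep = av.recovery_report(clean_cohort.truth_table,
                                 clean_cohort.truth_table)
        assert np.allclose(rep["bias"], 0.0)
        assert np.allclose(rep["rmse"], 0.0)

    def test_constant_shift_appears_as_bias(self, clean_cohort):
        shifted = clean_cohort.truth_table.copy()
        cols = [c for c in shifted.columns if c not in ("animal_id", "group")]
        shifted[cols] = shifted[cols] + 2.5
        rep = av.recovery_report(clean_cohort.truth_table, shifted)
        assert np.allclose(rep["bias"], 2.5)

    def test_id_mismatch(self, clean_cohort):
        bad = clean_cohort.truth_table.copy()
        bad.loc[0, "animal_id"] = "ghost"
        with pytest.raises(AlignmentError, match="ghost"):
            av.recovery_report(clean_cohort.truth_table, bad)


class TestMonteCarloEngine:
    def test_matches_record_level_at_zero_noise(self, control):
        """Both engines reduce to the same exact fluxes without noise."""
        config = av.SimCohortConfig(
            seed=3, n_per_group=2, noise=av.NoiseModel(0, 0, 0, 0),
            variation=av.BetweenAnimalVariation(0, 0, 0, 0, 0, 0))
        mc = av.cohort_flux_monte_carlo(config, n_reps=2)
        sim = av.simulate_cohort(config)
        res = av.analyze_cohort(sim.samples)
        for flux in FLUX_FIELDS:
            control_cols = mc["groups"] == "control"
            assert np.allclose(mc["estimates"][flux][:, control_cols],
                               av.true_fluxes(config.control)[flux])
            got = res.kinetics.loc[res.kinetics.group == "control", flux]
            assert np.allclose(got, av.true_fluxes(config.control)[flux])

    def test_rmse_monotone_in_noise(self):
        """Recovery error cannot improve when every noise SD grows."""
        rmses = []
        for scale in (0.5, 1.0, 2.0):
            config = av.SimCohortConfig(seed=21,
                                        noise=av.NoiseModel().scaled(scale))
            b = av.monte_carlo_bias(config, n_reps=500, rng=21)
            rmses.append(b.set_index("flux")["rmse"])
        for lo, hi in zip(rmses, rmses[1:]):
            assert (hi >= lo * 0.999).all()

    def test_antithetic_preserves_marginals(self):
        config = av.SimCohortConfig(seed=2)
        plain = av.cohort_flux_monte_carlo(config, 2000, rng=1)
        anti = av.cohort_flux_monte_carlo(config, 2000, rng=1,
                                          antithetic=True)
        for flux in ("protein_synthesis", "net_uptake"):
            a = plain["estimates"][flux].ravel()
            b = anti["estimates"][flux].ravel()
            assert np.mean(b) == pytest.approx(np.mean(a),
                                               abs=4 * np.std(a)
                                               / np.sqrt(a.size))

    def test_null_pvalues_roughly_uniform(self):
        p = av.null_pvalues(2000, seed=5)
        assert 0.02 < np.mean(p < 0.05) < 0.09
        assert 0.4 < np.mean(p < 0.5) < 0.6
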