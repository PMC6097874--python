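"""Generator calibration, determinism and null behaviour."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from wormlead import lifespan as ls
from wormlead import nmrquant as nq
from wormlead import seizure as sz
from wormlead import synthgen as sg
from wormlead import wormstats as ws
from wormlead.errors import ValidationError


class TestDeterminism:
    def test_same_seed_same_tables(self):
        for gen in (sg.gen_seizure, sg.gen_neurons, sg.gen_bends):
            a, b = gen(seed=5), gen(seed=5)
            pd.testing.assert_frame_equal(a, b)

    def test_lifespan_records_reproducible(self):
        assert sg.gen_lifespans(seed=5) == sg.gen_lifespans(seed=5)
        assert sg.gen_lifespans(seed=5) != sg.gen_lifespans(seed=6)

    def test_child_seed_stable_and_bounded(self):
        assert sg.child_seed(17, "seizure") == sg.child_seed(17, "seizure")
        assert sg.child_seed(17, "seizure") != sg.child_seed(17, "lifespan")
        assert 0 <= sg.child_seed(2**30, "x") < 2**31


class TestGompertzCalibration:
    @pytest.mark.parametrize("target", [8.0, 11.51, 14.37, 20.0])
    def test_quadrature_oracle(self, target):
        shape = 0.35
        rate = sg.calibrate_gompertz(target, shape)
        with np.errstate(over="ignore"):  # exp overflow in the far tail -> S = 0
            mean, _ = integrate.quad(
                lambda t: np.exp(-(rate / shape) * (np.exp(shape * t) - 1.0)),
                0, np.inf, limit=200,
            )
        assert mean == pytest.approx(target, abs=1e-6)

    def test_monotone_in_target(self):
        assert sg.calibrate_gompertz(20.0, 0.35) < sg.calibrate_gompertz(10.0, 0.35)

    def test_small_shape_limit_is_exponential(self):
        rate = sg.calibrate_gompertz(10.0, 1e-6)
        assert rate == pytest.approx(0.1, rel=1e-3)  # exponential mean 1/rate

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            sg.calibrate_gompertz(-1.0, 0.35)


class TestLifespanGenerator:
    def test_zero_censor_rate_all_die(self):
        scen = sg.LifespanScenario(
            groups={"only": sg.LifespanGroup(11.51, 60, 0.0)}
        )
        records = sg.gen_lifespans(scen, seed=3)
        assert all(r.status == "died" for r in records)

    def test_dmso_cohort_hits_target_mean(self):
        records = sg.gen_lifespans(seed=11)
        out = ls.mean_lifespan([r for r in records if r.group == "DMSO"])
        assert abs(out.mean_days - 11.51) < 2 * out.sem

    def test_all_groups_within_two_sem_of_targets(self):
        scen = sg.LifespanScenario()
        records = sg.gen_lifespans(scen, seed=12)
        for group, cfg in scen.groups.items():
            out = ls.mean_lifespan([r for r in records if r.group == group])
            assert abs(out.mean_days - cfg.target_mean) < 2 * out.sem, group

    def test_daf16_scenario_drug_effect_collapses(self):
        scen = sg.daf16_lifespan_scenario()
        targets = {g: c.target_mean for g, c in scen.groups.items()}
        assert abs(targets["MPS"] - targets["DMSO"]) < 0.5

    def test_death_days_land_on_scoring_grid(self):
        records = sg.gen_lifespans(seed=7)
        assert all(r.last_day_alive % 2 == 1 for r in records)  # days 1,3,5,...

    def test_mps_longevity_effect_power(self):
        # with the default effect, log-rank DMSO vs MPS is significant in
        # >= 95 of 100 seeded replicates
        hits = 0
        for seed in range(100):
            records = sg.gen_lifespans(seed=seed)
            _, p = ls.logrank(
                [r for r in records if r.group == "DMSO"],
                [r for r in records if r.group == "MPS"],
            )
            hits += p < 0.05
        assert hits >= 95


class TestSeizureGenerator:
    def test_flat_truth_keeps_vehicle_rate(self):
        scen = sg.SeizureScenario(ec50_molar={"inert": None})
        data = sg.gen_seizure(scen, seed=2)
        summary = sz.summarise(data)
        drug = summary[summary.compound_id == "inert"]
        vehicle = summary[summary.compound_id == "vehicle"]
        assert (drug.pct_seizing > 90).all()
        assert drug.mean_bobs.mean() == pytest.approx(vehicle.mean_bobs.iloc[0], rel=0.15)

    def test_ec50_recovery_within_ten_percent_median(self):
        truth = 9.7e-3
        recovered = []
        for seed in range(40):
            data = sg.gen_seizure(sg.SeizureScenario(ec50_molar={"cpd1": truth}), seed=seed)
            summary = sz.summarise(data)
            veh = summary[summary.conc_molar == 0]
            drug = summary[summary.compound_id == "cpd1"]
            fit = sz.fit_4pl(
                np.concatenate([veh.conc_molar, drug.conc_molar]),
                np.concatenate([veh.mean_bobs, drug.mean_bobs]),
            )
            recovered.append(fit.ec50)
        assert abs(np.median(recovered) - truth) / truth < 0.10

    def test_toxicity_rises_with_concentration(self):
        scen = sg.SeizureScenario(ec50_molar={"cpd1": 9.7e-3}, tox_ec50=0.02)
        data = sg.gen_seizure(scen, seed=9)
        summary = sz.summarise(data)
        drug = summary[summary.compound_id == "cpd1"].sort_values("conc_molar")
        assert drug.pct_toxic.iloc[-1] > drug.pct_toxic.iloc[0]


class TestNeuronGenerator:
    def test_intact_worm_has_nineteen_bodies(self):
        scen = sg.NeuronScenario(groups={"WT": sg.NeuronGroup(0.0, 0.0, 10)})
        frame = sg.gen_neurons(scen, seed=1)
        assert (frame.cell_bodies == ws.N_DTYPE_NEURONS).all()
        assert (frame.breaks == 0).all()

    def test_wt_defaults_stay_intact_to_day_seven(self):
        frame = sg.gen_neurons(seed=6)
        day7 = frame[(frame.group == "WT") & (frame.age_day == 7)]
        assert day7.cell_bodies.mean() > 18.5

    def test_tdp43_loses_from_day_one(self):
        frame = sg.gen_neurons(seed=6)
        wt = frame[(frame.group == "WT") & (frame.age_day == 1)]
        tdp = frame[(frame.group == "TDP43_DMSO") & (frame.age_day == 1)]
        assert tdp.cell_bodies.mean() < wt.cell_bodies.mean()
        assert tdp.breaks.mean() > wt.breaks.mean()

    def test_mps_reduces_breaks_at_day_five(self):
        frame = sg.gen_neurons(seed=8)
        sub = frame[frame.age_day == 5]
        means = sub.groupby("group").breaks.mean()
        assert means["TDP43_MPS"] < means["TDP43_DMSO"]

    def test_daf16_scenario_removes_protection(self):
        scen = sg.daf16_neuron_scenario()
        assert scen.groups["TDP43_MPS"] == scen.groups["TDP43_DMSO"]


class TestBendsGenerator:
    def test_zero_dispersion_limit_is_poisson(self):
        scen = sg.BendsScenario(
            group_multipliers={"g": 1.0}, baseline_by_age={1: 8.0},
            dispersion=0.0, n_per_group_age=4000,
        )
        frame = sg.gen_bends(scen, seed=3)
        mean, var = frame.bends_per_min.mean(), frame.bends_per_min.var()
        assert var == pytest.approx(mean, rel=0.1)

    def test_dispersion_inflates_variance(self):
        scen = sg.BendsScenario(
            group_multipliers={"g": 1.0}, baseline_by_age={1: 8.0},
            dispersion=0.5, n_per_group_age=4000,
        )
        frame = sg.gen_bends(scen, seed=3)
        mean, var = frame.bends_per_min.mean(), frame.bends_per_min.var()
        assert var == pytest.approx(mean * (1 + 0.5 * mean), rel=0.15)

    def test_dose_zero_is_vehicle_baseline(self):
        assert sg.mps_dose_multiplier(0.0) == 1.0

    def test_inverted_u_dose_response(self):
        assert sg.mps_dose_multiplier(5e-5) > sg.mps_dose_multiplier(2e-3)
        assert sg.mps_dose_multiplier(5e-5) > 1.0
        assert sg.mps_dose_multiplier(2e-3) < 1.0


class TestSpectrumGenerator:
    def test_zero_truth_leaves_only_background(self):
        scen = sg.SpectrumScenario(truth_internal_molar=0.0)
        bg = sg.default_metabolite_background()
        sample, _ = sg.gen_spectrum(scen, background=bg)
        blank = sg.background_spectrum(scen, bg)
        assert np.allclose(sample.intensity, blank.intensity)

    def test_succinimide_and_ethosuximide_detectable(self):
        bg = sg.default_metabolite_background()
        for cid, truth in (("cpd2", 206.6e-6), ("cpd1", 143.8e-6)):
            scen = sg.SpectrumScenario(
                compound_id=cid, windows=sg.DEFAULT_WINDOWS[cid], truth_internal_molar=truth
            )
            sample, _ = sg.gen_spectrum(scen, background=bg)
            blank = sg.background_spectrum(scen, bg)
            detected, _ = nq.detectability(sample, scen.windows[0], blank)
            assert detected, cid

    def test_mps_windows_occluded(self):
        bg = sg.default_metabolite_background()
        scen = sg.SpectrumScenario(
            compound_id="cpd9", windows=sg.DEFAULT_WINDOWS["cpd9"],
            truth_internal_molar=1.25e-6,
        )
        sample, _ = sg.gen_spectrum(scen, background=bg)
        blank = sg.background_spectrum(scen, bg)
        for w in scen.windows:
            detected, diag = nq.detectability(sample, w, blank)
            assert not detected and diag["occluded"], w

    def test_window_overlapping_tsp_rejected(self):
        scen = sg.SpectrumScenario(
            windows=(nq.PeakWindow("x", -0.02, 0.1, protons=1),)
        )
        with pytest.raises(ValidationError):
            sg.gen_spectrum(scen)


class TestNullUniformity:
    def test_logrank_p_uniform_under_null(self):
        # two exchangeable cohorts (same Gompertz target, no effect)
        pvals = []
        scen = sg.LifespanScenario(
            groups={
                "a": sg.LifespanGroup(11.51, 60, 0.2),
                "b": sg.LifespanGroup(11.51, 60, 0.2),
            }
        )
        for seed in range(200):
            records = sg.gen_lifespans(scen, seed=seed)
            _, p = ls.logrank(
                [r for r in records if r.group == "a"],
                [r for r in records if r.group == "b"],
            )
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_kruskal_p_uniform_under_label_permutation(self):
        scen = sg.BendsScenario(
            group_multipliers={"a": 1.0, "b": 1.0, "c": 1.0},
            baseline_by_age={5: 6.0}, n_per_group_age=20,
        )
        pvals = []
        for seed in range(200):
            frame = sg.gen_bends(scen, seed=seed)
            rng = np.random.default_rng(seed)
            labels = rng.permutation(frame.group.to_numpy())
            groups = [
                frame.bends_per_min.to_numpy()[labels == g] for g in ("a", "b", "c")
            ]
            _, p = ws.kruskal_wallis(*groups)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
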