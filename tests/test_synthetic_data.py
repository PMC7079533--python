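"""Generator contracts: waveforms, pump, stage traces, occlusion, saline, cohorts."""

import numpy as np
import pytest

from pvshock import synthetic_data as sd
from pvshock.errors import (
    InsufficientDataError,
    InvalidPresetError,
    NonConvergenceError,
)
from pvshock.presets import BLINDED_DRUG_STAGES, StagePreset


class TestElastanceWaveform:
    def test_starts_at_diastolic_stiffness(self, presets):
        p = presets["baseline"]
        assert sd.elastance_waveform(0.0, p) == pytest.approx(p.Emin)

    def test_peak_equals_emax_and_period(self, presets):
        p = presets["baseline"]
        T = 60.0 / p.HR
        t = np.linspace(0, T, 20001, endpoint=False)
        e = sd.elastance_waveform(t, p)
        assert e.max() == pytest.approx(p.Emax, rel=1e-5)
        assert e.min() == pytest.approx(p.Emin, rel=1e-6)
        # periodicity
        assert sd.elastance_waveform(0.3 * T + T, p) == pytest.approx(
            sd.elastance_waveform(0.3 * T, p))

    def test_period_matches_heart_rate(self, presets):
        assert 60.0 / presets["baseline"].with_(HR=82.0).HR == pytest.approx(0.7317, abs=1e-4)


class TestPumpFlow:
    def test_level_zero_gives_no_flow(self):
        assert sd.pump_flow(55.0, 0.0) == 0.0

    def test_max_flow_at_zero_head(self):
        assert sd.pump_flow(0.0, 1.0) == pytest.approx(3.5)

    def test_monotone_non_increasing_in_head(self):
        heads = np.linspace(-20, 200, 50)
        q = sd.pump_flow(heads, 1.0)
        assert np.all(np.diff(q) <= 1e-12)
        assert np.all(q >= 0)

    def test_invalid_level_rejected(self):
        with pytest.raises(InvalidPresetError):
            sd.pump_flow(10.0, 1.5)


class TestSimulateStage:
    def test_deterministic_for_fixed_seed(self, presets):
        a = sd.simulate_stage(presets["cs"], duration=8.0, seed=3)
        b = sd.simulate_stage(presets["cs"], duration=8.0, seed=3)
        assert np.array_equal(a.p_lv, b.p_lv)
        assert np.array_equal(a.v, b.v)

    def test_volume_conservation_over_cycle(self, baseline_trace_clean):
        """Steady state: net volume change over one cycle is ~0 (|dV| < 0.1 mL)."""
        n_cyc = baseline_trace_clean.truth.extras["n_cycle_samples"]
        v = baseline_trace_clean.truth.v_true
        assert abs(v[n_cyc] - v[0]) < 0.1

    def test_loop_is_counterclockwise_with_positive_area(self, baseline_trace_clean):
        n_cyc = baseline_trace_clean.truth.extras["n_cycle_samples"]
        v = baseline_trace_clean.truth.v_true[:n_cyc]
        p = baseline_trace_clean.p_lv[:n_cyc]
        signed = 0.5 * (np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1)))
        # counterclockwise traversal in the (V, P) plane => positive signed area
        assert signed > 0

    def test_calibration_identity_on_raw_channel(self, presets):
        tr = sd.simulate_stage(presets["baseline"], duration=8.0, seed=5,
                               noise_pressure=0.0, noise_volume=0.0,
                               alpha_true=1.3, Vc_true=50.0)
        rebuilt = tr.v / 1.3 - 50.0
        assert np.allclose(rebuilt, tr.truth.v_true, atol=1e-9)

    def test_no_contraction_collapses_loop(self, presets):
        p = presets["baseline"].with_(Emax=0.1181, Emin=0.118)
        tr = sd.simulate_stage(p, duration=8.0, seed=0,
                               noise_pressure=0.0, noise_volume=0.0)
        assert tr.truth.stage_means["SW"] < 1.0

    def test_full_support_closes_aortic_valve_in_some_animals(self):
        coh = sd.simulate_cohort(n_pigs=10, seed=1, level="summary")
        imp = coh.records[coh.records["stage"] == "impella"]
        assert (~imp["valve_open_true"]).sum() >= 1

    def test_too_short_duration_rejected(self, presets):
        with pytest.raises(InsufficientDataError):
            sd.simulate_stage(presets["baseline"], duration=2.0, seed=0)


class TestIvcOcclusion:
    def test_edv_strictly_decreasing(self, occlusion_trace_clean):
        edv = occlusion_trace_clean.truth.extras["edv_per_beat"]
        assert all(b < a for a, b in zip(edv[1:], edv[2:]))

    def test_zero_decay_gives_identical_beats(self, presets):
        tr = sd.simulate_ivc_occlusion(presets["baseline"], n_beats=6,
                                       preload_decay=0.0, seed=0,
                                       noise_pressure=0.0, noise_volume=0.0)
        pts = np.array(tr.truth.extras["es_points"])
        # identical up to the residual settling transient
        assert np.ptp(pts[:, 0]) < 1e-4

    def test_es_points_on_espvr_line(self, occlusion_trace_clean):
        tr = occlusion_trace_clean
        for esv, esp in tr.truth.extras["es_points"]:
            assert esp == pytest.approx(
                tr.truth.Ees_true * (esv - tr.truth.V0_true), abs=1e-9)

    def test_excessive_decay_truncates_with_flag(self, presets):
        with pytest.warns(UserWarning, match="truncated"):
            tr = sd.simulate_ivc_occlusion(
                presets["baseline"], n_beats=40, preload_decay=0.19, seed=0,
                noise_pressure=0.0, noise_volume=0.0)
        assert tr.truth.extras["truncated"]


class TestSalineBolus:
    def test_true_volume_unchanged_by_bolus(self, saline_trace_clean, presets):
        n_cyc = saline_trace_clean.truth.extras["n_cycle_samples"]
        v = saline_trace_clean.truth.v_true
        first, last = v[:n_cyc], v[-n_cyc:]
        assert np.allclose(first, last, atol=0.05)

    def test_raw_channel_rises_during_washin(self, saline_trace_clean):
        ex = saline_trace_clean.truth.extras
        n_cyc = ex["n_cycle_samples"]
        means = [saline_trace_clean.v[k * n_cyc:(k + 1) * n_cyc].mean()
                 for k in range(len(ex["s_per_beat"]))]
        pre, peak = means[0], max(means)
        assert peak > pre * 1.2

    def test_short_bolus_rejected(self, presets):
        with pytest.raises(InsufficientDataError):
            sd.simulate_saline_bolus(presets["baseline"], bolus_span=3)


class TestShockInduction:
    def test_stops_at_stated_criterion(self, presets):
        shocked, n = sd.emulate_shock_induction(presets["baseline"], 0.15)
        base = sd.stage_truth(presets["baseline"])
        tr = sd.stage_truth(shocked)
        ci = tr["CO_lmin"] / sd.BSA_M2
        assert (tr["SvO2"] < 30.0 or tr["SvO2"] <= 0.5 * base["SvO2"] or ci < 1.5)
        # one step earlier the criterion did not hold yet
        prev = shocked.with_(Emax=shocked.Emax / (1.0 - 0.15))
        tp = sd.stage_truth(prev)
        assert not (tp["SvO2"] < 30.0 or tp["SvO2"] <= 0.5 * base["SvO2"]
                    or tp["CO_lmin"] / sd.BSA_M2 < 1.5)

    def test_large_steps_converge_quickly(self, presets):
        _, n = sd.emulate_shock_induction(presets["baseline"], 0.45)
        assert n <= 5

    def test_smaller_steps_need_more_injections(self, presets):
        _, n_small = sd.emulate_shock_induction(presets["baseline"], 0.05)
        _, n_large = sd.emulate_shock_induction(presets["baseline"], 0.30)
        assert n_small > n_large

    def test_unreachable_criterion_raises(self, presets):
        lazy = presets["baseline"].with_(VO2=1.0)  # nearly no O2 demand
        with pytest.raises(NonConvergenceError):
            sd.emulate_shock_induction(lazy, 0.01, max_steps=5)


class TestBloodGas:
    def test_fick_linearity_in_flow(self, presets):
        p = presets["baseline"]
        g1 = sd.sample_blood_gas(p, 3.0)
        g2 = sd.sample_blood_gas(p, 6.0)
        d1 = g1["SaO2"] - g1["SvO2"]
        d2 = g2["SaO2"] - g2["SvO2"]
        assert d2 == pytest.approx(d1 / 2.0)

    def test_zero_consumption_gives_arterial_saturation(self, presets):
        p = presets["baseline"].with_(VO2=0.0)
        g = sd.sample_blood_gas(p, 4.0)
        assert g["SvO2"] == pytest.approx(g["SaO2"])

    def test_baseline_svo2_matches_reference(self, presets):
        truth = sd.stage_truth(presets["baseline"])
        assert truth["SvO2"] == pytest.approx(76.0, rel=0.10)

    def test_lactate_rises_only_below_critical_delivery(self, presets):
        p = presets["cs"]
        low = sd.sample_blood_gas(p, 1.5)
        high = sd.sample_blood_gas(p, 6.0)
        assert low["arterial_lactate"] > high["arterial_lactate"]
        assert high["arterial_lactate"] == pytest.approx(1.4, abs=1e-9)


class TestCohort:
    def test_reproducible_from_seed(self):
        a = sd.simulate_cohort(n_pigs=4, seed=9, level="summary")
        b = sd.simulate_cohort(n_pigs=4, seed=9, level="summary")
        assert a.records.equals(b.records)
        assert a.stage_order == b.stage_order

    def test_design_invariants(self, summary_cohort):
        rec = summary_cohort.records
        assert set(rec.groupby("pig_id").size()) == {7}
        for pig, order in summary_cohort.stage_order.items():
            assert order[-1] == "impella_phenyl"
            assert sorted(order[3:6]) == sorted(BLINDED_DRUG_STAGES)

    def test_drug_orders_are_permutations(self):
        coh = sd.simulate_cohort(n_pigs=30, seed=5, level="summary")
        perms = {tuple(o[3:6]) for o in coh.stage_order.values()}
        assert perms <= {tuple(np.array(BLINDED_DRUG_STAGES)[list(p)])
                         for p in __import__("itertools").permutations(range(3))}
        assert len(perms) >= 4  # several of the 6 orders appear

    def test_invalid_preset_rejected(self):
        with pytest.raises(InvalidPresetError):
            StagePreset(stage_label="baseline", Emax=0.1, Emin=0.2, V0_true=17,
                        HR=80, SVR=1.0, Cart=1.0, venous_pressure=15,
                        pump_level=0.0, VO2=160.0)
        with pytest.raises(InvalidPresetError):
            StagePreset(stage_label="baseline", Emax=1.4, Emin=0.12, V0_true=17,
                        HR=300, SVR=1.0, Cart=1.0, venous_pressure=15,
                        pump_level=0.0, VO2=160.0)
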