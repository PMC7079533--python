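"""Self-validation studies: parameter recovery, coverage, sign patterns.

These functions re-derive the quantities the package's acceptance checks
rest on, from scratch, by running the generator and the estimators:
in-table energy identities, shoelace refinement, ESPVR and saline-bolus
parameter recovery, mixed-model identifiability and CI coverage, and the
qualitative sign pattern of the stage/drug effects.  Both the test suite
and ``scripts/acceptance.py`` call into this module.
"""

from __future__ import annotations

import numpy as np

from . import calibration as cal
from . import pv_metrics as pv
from . import stats as st
from . import synthetic_data as sd
from .presets import default_presets
from .reference import TABLE1


def table_pva_identities() -> dict:
    """PVA = SW + PE recomputed from the reference stage means."""
    out = {}
    for stage in ("baseline", "cs", "impella"):
        out[stage] = pv.pva(TABLE1["SW"][stage]["mean"], TABLE1["PE"][stage]["mean"])
    return out


def table_pe_reduction_pct() -> float:
    """Percent reduction of mean PE from shock to pump support (reference means)."""
    pe_cs = TABLE1["PE"]["cs"]["mean"]
    pe_imp = TABLE1["PE"]["impella"]["mean"]
    return 100.0 * (pe_cs - pe_imp) / pe_cs


def rectangle_sw() -> float:
    """Shoelace stroke work of the canonical rectangular loop (P 10-110, V 50-130)."""
    v = np.array([130.0, 50.0, 50.0, 130.0])
    p = np.array([10.0, 10.0, 110.0, 110.0])
    return pv.stroke_work(v, p)


def refinement_relative_error(fs: float = 250.0, factor: int = 4,
                              stage: str = "baseline") -> float:
    """Relative SW difference between fs and factor*fs on a noise-free beat."""
    preset = default_presets()[stage]
    sws = []
    for f in (fs, fs * factor):
        tr = sd.simulate_stage(preset, duration=10.0, fs=f, seed=0,
                               noise_pressure=0.0, noise_volume=0.0,
                               alpha_true=1.0, Vc_true=0.0)
        c = cal.apply_calibration(
            tr, cal.CalibrationResult(alpha=1.0, Vc=0.0, V0=preset.V0_true))
        beats = pv.beats_from_trace(c, preset.V0_true)
        sws.append(pv.summarize_stage(beats, preset.V0_true).SW)
    return abs(sws[1] - sws[0]) / sws[1]


def espvr_recovery_errors(seed: int = 0) -> dict:
    """Noise-free occlusion: |fit - truth| for (Ees, V0)."""
    preset = default_presets()["baseline"]
    tr = sd.simulate_ivc_occlusion(preset, n_beats=10, preload_decay=0.05,
                                   seed=seed, noise_pressure=0.0, noise_volume=0.0,
                                   alpha_true=1.0, Vc_true=0.0)
    ees, v0, _ = cal.espvr_from_trace(tr)
    return {"ees_abs_err": abs(ees - tr.truth.Ees_true),
            "v0_abs_err": abs(v0 - tr.truth.V0_true),
            "ees_true": tr.truth.Ees_true}


def saline_recovery_study(n_seeds: int = 100, vc_true: float = 50.0,
                          seed0: int = 0) -> dict:
    """Vc recovery at default noise over many seeded boluses."""
    preset = default_presets()["baseline"]
    errs = []
    for s in range(seed0, seed0 + n_seeds):
        tr = sd.simulate_saline_bolus(preset, Vc_true=vc_true, seed=s,
                                      alpha_true=sd.DEFAULT_ALPHA_TRUE)
        vc, _ = cal.estimate_parallel_conductance(tr, alpha=sd.DEFAULT_ALPHA_TRUE)
        errs.append(abs(vc - vc_true))
    errs = np.array(errs)
    return {"median_abs_err": float(np.median(errs)),
            "p90_abs_err": float(np.percentile(errs, 90)),
            "n": n_seeds}


def lmm_noise_free_error(n_pigs: int = 8, seed: int = 0,
                         variable: str = "cardiac_work_e3",
                         reference: str = "impella") -> float:
    """Max |contrast - injected effect| on a noise-free balanced cohort."""
    zero_bp = {k: 0.0 for k in sd.DEFAULT_BETWEEN_PIG_SD}
    zero_rn = {k: 0.0 for k in sd.DEFAULT_RECORD_NOISE}
    coh = sd.simulate_cohort(n_pigs=n_pigs, seed=seed, level="summary",
                             between_pig_sd=zero_bp, record_noise=zero_rn)
    r = coh.records
    effs = st.fit_stage_lmm(r, variable, reference)
    truth_by_stage = r.groupby("stage")[f"{variable}_true"].mean()
    ref_truth = truth_by_stage[reference]
    errs = [abs(e.mean_difference - (truth_by_stage[e.stage] - ref_truth))
            for e in effs if e.stage != reference]
    return float(max(errs))


def population_effect(variable: str, stage: str, reference: str = "impella",
                      n_draws: int = 1000, seed: int = 12345) -> float:
    """Population-average stage effect under the between-pig distribution.

    Large-N Monte Carlo over random pig parameter draws of the noise-free
    per-pig effect (stage truth minus reference truth); the estimand of the
    crossover contrast.
    """
    presets = default_presets()
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_draws):
        draws = sd.draw_pig_parameters(rng, sd.DEFAULT_BETWEEN_PIG_SD)
        t_s = sd.stage_truth(sd.perturb_preset(presets[stage], draws))
        t_r = sd.stage_truth(sd.perturb_preset(presets[reference], draws))
        diffs.append(t_s[variable] - t_r[variable])
    return float(np.mean(diffs))


def coverage_study(n_replicates: int = 200, n_pigs: int = 10,
                   variable: str = "cardiac_work_e3",
                   stage: str = "impella_dopa", reference: str = "impella",
                   seed: int = 0, n_truth_draws: int = 1000) -> dict:
    """Empirical 95% CI coverage of the mixed-model contrast.

    Truth is the population-average effect (one large Monte Carlo); each
    replicate simulates a fresh summary-level cohort at default noise, fits
    the heteroscedastic random-intercept model, and checks whether the Wald
    CI for ``stage`` vs ``reference`` contains the truth.
    """
    truth = population_effect(variable, stage, reference,
                              n_draws=n_truth_draws, seed=seed + 999_983)
    covered = 0
    est = []
    for i in range(n_replicates):
        coh = sd.simulate_cohort(n_pigs=n_pigs, seed=seed + 1 + i, level="summary")
        effs = st.fit_stage_lmm(coh.records, variable, reference)
        e = next(x for x in effs if x.stage == stage)
        est.append(e.mean_difference)
        if e.ci_lo <= truth <= e.ci_hi:
            covered += 1
    return {"coverage_pct": 100.0 * covered / n_replicates,
            "truth": truth, "mean_estimate": float(np.mean(est)),
            "n_replicates": n_replicates}


def sign_pattern(seed: int = 0) -> dict:
    """Qualitative stage/drug effect signs on the calibrated presets (noise-free).

    Checks, against the noise-free stage truths: SW falls at shock; PE falls
    by >= 40% under pump support; every catecholamine raises SW and cardiac
    work; phenylephrine raises PE and cardiac work but not SW; phenylephrine
    lowers SvO2 while the catecholamines raise it; phenylephrine raises
    arterial lactate.
    """
    presets = default_presets()
    t = {name: sd.stage_truth(p) for name, p in presets.items()}
    cats = ("impella_epi", "impella_dopa", "impella_nor")
    checks = {
        "sw_falls_at_cs": t["cs"]["SW"] < t["baseline"]["SW"],
        "pe_drop_impella_ge_40pct":
            (t["cs"]["PE"] - t["impella"]["PE"]) / t["cs"]["PE"] >= 0.40,
        "catecholamines_raise_sw":
            all(t[c]["SW"] > t["impella"]["SW"] for c in cats),
        "catecholamines_raise_cardiac_work":
            all(t[c]["cardiac_work"] > t["impella"]["cardiac_work"] for c in cats),
        "catecholamines_raise_svo2":
            all(t[c]["SvO2"] > t["impella"]["SvO2"] for c in cats),
        "phenylephrine_raises_pe":
            t["impella_phenyl"]["PE"] > t["impella"]["PE"],
        "phenylephrine_raises_cardiac_work":
            t["impella_phenyl"]["cardiac_work"] > t["impella"]["cardiac_work"],
        "phenylephrine_does_not_raise_sw":
            t["impella_phenyl"]["SW"] <= t["impella"]["SW"] * 1.05,
        "phenylephrine_lowers_svo2":
            t["impella_phenyl"]["SvO2"] < t["impella"]["SvO2"],
        "phenylephrine_raises_lactate":
            t["impella_phenyl"]["arterial_lactate"]
            > t["impella"]["arterial_lactate"],
    }
    checks["all_pass"] = all(checks.values())
    checks["pe_drop_pct"] = 100.0 * (t["cs"]["PE"] - t["impella"]["PE"]) / t["cs"]["PE"]
    return checks


def cs_downstream_summary(seed: int = 1) -> dict:
    """Full-chain stage summary of the calibrated shock preset.

    Simulates the nominal cardiogenic-shock stage at default noise, applies
    the true calibration constants, segments beats and summarizes — the
    estimate the pipeline would report for an average animal at shock onset.
    """
    preset = default_presets()["cs"]
    tr = sd.simulate_stage(preset, duration=30.0, seed=seed)
    c = cal.apply_calibration(
        tr, cal.CalibrationResult(alpha=sd.DEFAULT_ALPHA_TRUE,
                                  Vc=sd.DEFAULT_VC_TRUE, V0=preset.V0_true))
    m = pv.summarize_stage(pv.beats_from_trace(c, preset.V0_true),
                           preset.V0_true)
    return {"SW": m.SW, "PVA": m.PVA, "HR": m.HR, "PE": m.PE}


def baseline_cohort_mean_sw(seed: int = 0, n_pigs: int = 10,
                            n_cohorts: int = 10) -> float:
    """Baseline-stage mean stroke work pooled over a few simulated cohorts.

    Pooling reduces the Monte-Carlo error of the check below the between-pig
    sampling noise of a single ten-animal cohort.
    """
    vals = []
    for i in range(n_cohorts):
        coh = sd.simulate_cohort(n_pigs=n_pigs, seed=seed + i, level="summary")
        vals.append(coh.records.loc[coh.records["stage"] == "baseline", "SW"])
    return float(np.concatenate(vals).mean())


def simulated_stage_means(seed: int = 0, n_pigs: int = 10) -> dict:
    """Cohort-level stage means of the headline variables (summary tier)."""
    coh = sd.simulate_cohort(n_pigs=n_pigs, seed=seed, level="summary")
    g = coh.records.groupby("stage")
    return {
        "sw_baseline": float(g["SW"].mean()["baseline"]),
        "sw_cs": float(g["SW"].mean()["cs"]),
        "pva_cs": float(g["PVA"].mean()["cs"]),
        "pva_impella": float(g["PVA"].mean()["impella"]),
        "hr_cs": float(g["HR"].mean()["cs"]),
        "svo2_baseline": float(g["SvO2"].mean()["baseline"]),
        "svo2_cs": float(g["SvO2"].mean()["cs"]),
        "svo2_impella": float(g["SvO2"].mean()["impella"]),
        "cardiac_work_e3_impella": float(g["cardiac_work_e3"].mean()["impella"]),
    }
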