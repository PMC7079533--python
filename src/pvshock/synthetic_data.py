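"""Synthetic porcine hemodynamics with known ground truth.

Generates everything the downstream analysis consumes: steady-state stage
traces (elastance ventricle + Windkessel + axial-flow pump), caval-occlusion
runs for ESPVR fitting, hypertonic-saline boluses for parallel-conductance
calibration, a stepwise shock-induction procedure, Fick-balance blood-gas
panels, and full crossover cohorts with randomized blinded drug order.

Raw-volume convention (forward model): ``v_raw = alpha_true * (v_true + Vc_true)
+ noise``; during a saline bolus the blood component gains a per-beat factor
``(1 + s_k)`` while the parallel (wall) component is unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import engine
from .errors import (
    InsufficientDataError,
    InvalidPresetError,
    NonConvergenceError,
    SimulationFailureError,
)
from .presets import BLINDED_DRUG_STAGES, STAGE_LABELS, StagePreset, default_presets
from .types import CohortDataset, GeneratorTruth, SignalTrace

import pandas as pd

# Hemoglobin O2 binding: 1.34 mL O2 per g Hb; 1 mmol/L Hb (monomer) = 16.114 g/L.
O2_PER_HB = 1.34 * 16.114  # mL O2 per L blood per (mmol/L Hb) at 100% saturation

#: body surface area used for cardiac index, m^2 (~70 kg pig)
BSA_M2 = 1.2

DEFAULT_FS = 250.0
DEFAULT_ALPHA_TRUE = 1.3
DEFAULT_VC_TRUE = 50.0
DEFAULT_NOISE_PRESSURE = 1.0  # mmHg (sd, additive Gaussian)
DEFAULT_NOISE_VOLUME = 2.0    # mL in raw units (sd)


def elastance_waveform(t_in_cycle, preset: StagePreset):
    """Time-varying elastance E(t), mmHg/mL, period 60/HR, range [Emin, Emax]."""
    if preset.HR <= 0:
        raise InvalidPresetError("HR must be positive")
    T = 60.0 / preset.HR
    s = np.asarray(t_in_cycle, dtype=float) / T
    return preset.Emin + (preset.Emax - preset.Emin) * engine.activation(s)


def pump_flow(head_pressure, pump_level: float, qmax_lmin: float = 3.5,
              k_lmin_per_mmhg: float = 0.02):
    """Axial-pump flow (L/min) from a linear head-flow curve, floored at 0.

    At zero head and full level the flow equals the configured maximum; flow
    is monotonically non-increasing in head and capped at ``qmax * level``.
    """
    if not (0.0 <= pump_level <= 1.0):
        raise InvalidPresetError(f"pump_level must be in [0, 1], got {pump_level}")
    q = qmax_lmin * pump_level - k_lmin_per_mmhg * np.asarray(head_pressure, dtype=float)
    return np.clip(q, 0.0, qmax_lmin * pump_level)


def _snap_cycle(hr: float, fs: float) -> tuple[int, float, float]:
    """Cycle length snapped to an integer number of output samples."""
    n = int(round(fs * 60.0 / hr))
    if n < 4:
        raise InvalidPresetError(f"HR {hr} too fast for fs {fs}")
    T = n / fs
    return n, T, 60.0 / T


def _run(preset: StagePreset, n_out: int, fs: float, t_cycle: float,
         pven: np.ndarray, substeps: int = 8) -> dict:
    qmax_mls = preset.pump_qmax_lmin * preset.pump_level * 1000.0 / 60.0
    k_mls = preset.pump_k_lmin_per_mmhg * 1000.0 / 60.0
    out = engine.integrate_stage(
        n_out=n_out, fs=fs, t_cycle=t_cycle,
        emax=preset.Emax, emin=preset.Emin, v0=preset.V0_true,
        r_mv=preset.R_mv, r_av=preset.R_av, svr=preset.SVR, cart=preset.Cart,
        rap=preset.rap, pven=pven,
        q_pump_max_mls=qmax_mls, pump_k_mls_per_mmhg=k_mls,
        v_init=preset.V0_true + preset.venous_pressure / preset.Emin,
        pao_init=70.0, substeps=substeps,
    )
    if out["fail_index"] >= 0:
        raise SimulationFailureError(
            f"integration diverged at sample {out['fail_index']} for stage "
            f"{preset.stage_label!r} (Emax={preset.Emax}, Emin={preset.Emin}, "
            f"SVR={preset.SVR}, Cart={preset.Cart}, pump_level={preset.pump_level})"
        )
    return out


def _loop_area(v: np.ndarray, p: np.ndarray) -> float:
    """Shoelace area of the closed (V, P) polygon (independent truth-side copy)."""
    return 0.5 * abs(float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1))))


def _cycle_truth(preset: StagePreset, out: dict, sl: slice, t_cycle: float,
                 hr_actual: float) -> dict:
    """Noise-free stage summary computed from one steady-state cycle."""
    v = out["v"][sl]
    p = out["p_lv"][sl]
    pao = out["p_ao"][sl]
    e = out["e"][sl]
    qav = out["q_av"][sl]
    qp = out["q_pump"][sl]
    v0 = preset.V0_true
    es = int(np.argmax(e))
    edv, edp = float(v[0]), float(p[0])
    esv, esp = float(v[es]), float(p[es])
    sw = _loop_area(v, p)
    pe = esp * (esv - v0) / 2.0
    pva = sw + pe
    co_lmin = float(np.mean(qav + qp)) * 60.0 / 1000.0
    gas = sample_blood_gas(preset, co_lmin, seed=None)
    means = {
        "SW": sw, "PE": pe, "PVA": pva, "HR": hr_actual,
        "cardiac_work": hr_actual * pva, "cardiac_work_e3": hr_actual * pva / 1e3,
        "Ees": float(e[es]), "LVEDV": edv, "LVEDP": edp, "LVESV": esv, "LVESP": esp,
        "stroke_volume": edv - esv,
        "Ea": esp / (edv - esv) if edv > esv else np.nan,
        "MAP": float(np.mean(pao)), "RAP": preset.rap, "mPAP": preset.mpap,
        "CO_lmin": co_lmin, "valve_open": bool(np.max(qav) > 0),
    }
    means["Ea_over_Ees"] = means["Ea"] / means["Ees"]
    means.update({k: gas[k] for k in
                  ("SvO2", "renal_vO2", "cerebral_vO2", "arterial_lactate",
                   "venous_lactate", "Hb")})
    return means


def simulate_stage(
    preset: StagePreset,
    duration: float = 30.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    *,
    noise_pressure: float = DEFAULT_NOISE_PRESSURE,
    noise_volume: float = DEFAULT_NOISE_VOLUME,
    alpha_true: float = DEFAULT_ALPHA_TRUE,
    Vc_true: float = DEFAULT_VC_TRUE,
    settle_cycles: int = 20,
    substeps: int = 8,
) -> SignalTrace:
    """Periodic steady-state trace for one experimental stage.

    The simulation settles for ``settle_cycles`` before recording so that the
    net volume change over a recorded cycle is (numerically) zero.  Identical
    seeds give bit-identical traces.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    n_cyc, t_cycle, hr_actual = _snap_cycle(preset.HR, fs)
    if duration < 5 * t_cycle:
        raise InsufficientDataError("duration must cover at least 5 cycles")
    n_rec = int(round(duration * fs))
    n_settle = settle_cycles * n_cyc
    n_total = n_settle + n_rec
    pven = np.full(n_total, preset.venous_pressure)
    out = _run(preset, n_total, fs, t_cycle, pven, substeps)
    sl_rec = slice(n_settle, n_total)
    rec = {k: out[k][sl_rec] for k in ("v", "p_lv", "p_ao", "q_av", "q_pump", "e")}
    # last complete cycle of the recording for truth summaries
    k = n_rec // n_cyc
    sl_cycle = slice((k - 1) * n_cyc, k * n_cyc)
    means = _cycle_truth(preset, rec, sl_cycle, t_cycle, hr_actual)

    rng = np.random.default_rng(seed)
    p_lv = rec["p_lv"] + rng.normal(0.0, noise_pressure, n_rec)
    p_ao = rec["p_ao"] + rng.normal(0.0, noise_pressure, n_rec)
    v_raw = alpha_true * (rec["v"] + Vc_true) + rng.normal(0.0, noise_volume, n_rec)
    truth = GeneratorTruth(
        v_true=rec["v"].copy(), alpha_true=alpha_true, Vc_true=Vc_true,
        V0_true=preset.V0_true, Ees_true=means["Ees"], stage_means=means,
        extras={
            "hr_actual": hr_actual, "t_cycle": t_cycle, "n_cycle_samples": n_cyc,
            "valve_open": means["valve_open"], "co_lmin": means["CO_lmin"],
            "stage_label": preset.stage_label,
            # reference stroke volume a thermodilution-style measurement would give
            "reference_sv_ml": means["stroke_volume"],
        },
    )
    t = np.arange(n_rec) / fs
    return SignalTrace(t=t, p_lv=p_lv, v=v_raw, p_ao=p_ao, fs=fs, truth=truth)


def simulate_ivc_occlusion(
    preset: StagePreset,
    n_beats: int = 12,
    preload_decay: float = 0.05,
    seed: int = 0,
    *,
    fs: float = DEFAULT_FS,
    noise_pressure: float = DEFAULT_NOISE_PRESSURE,
    noise_volume: float = DEFAULT_NOISE_VOLUME,
    alpha_true: float = DEFAULT_ALPHA_TRUE,
    Vc_true: float = DEFAULT_VC_TRUE,
    settle_cycles: int = 20,
) -> SignalTrace:
    """Transient caval occlusion: venous pressure decays per beat.

    Successive beats have monotonically declining end-diastolic volume while
    every end-systolic point lies exactly on P = Ees_true * (V - V0_true)
    (up to the injected noise).  If the decay would push end-systolic volume
    to V0 the run is truncated and flagged in ``truth.extras['truncated']``.
    """
    if n_beats < 5:
        raise InsufficientDataError("n_beats must be >= 5")
    if not (0.0 <= preload_decay < 0.2):
        raise ValueError("preload_decay must be in [0, 0.2)")
    n_cyc, t_cycle, hr_actual = _snap_cycle(preset.HR, fs)
    n_settle = settle_cycles * n_cyc
    n_rec_beats = n_beats + 1  # one extra cycle so segmentation yields n_beats
    n_rec = n_rec_beats * n_cyc
    pven = np.full(n_settle + n_rec, preset.venous_pressure)
    for k in range(n_rec_beats):
        pv_k = preset.venous_pressure * (1.0 - preload_decay) ** k
        pven[n_settle + k * n_cyc: n_settle + (k + 1) * n_cyc] = pv_k
    out = _run(preset, n_settle + n_rec, fs, t_cycle, pven)
    rec = {k: out[k][n_settle:] for k in ("v", "p_lv", "p_ao", "q_av", "q_pump", "e")}

    # truncate when the preload has fallen so far that end-systolic volume
    # approaches V0 or the beat barely ejects (<1 mL): such beats sit on the
    # volume floor and are useless for ESPVR fitting
    truncated = False
    keep = n_rec_beats
    for k in range(n_rec_beats):
        cyc = slice(k * n_cyc, (k + 1) * n_cyc)
        ejected_ml = float(np.sum(rec["q_av"][cyc])) / fs
        if rec["v"][cyc].min() <= preset.V0_true + 2.0 or ejected_ml < 1.0:
            keep, truncated = k, True
            break
    if truncated:
        warnings.warn(
            f"occlusion truncated after {keep} beats: LVESV reached V0", stacklevel=2
        )
        if keep < 2:
            raise SimulationFailureError("preload_decay too large: no usable beats")
        n_rec = keep * n_cyc
        rec = {k: v[:n_rec] for k, v in rec.items()}

    es_off = int(np.argmax(rec["e"][:n_cyc]))
    n_kept = n_rec // n_cyc
    es_points = [
        (float(rec["v"][k * n_cyc + es_off]), float(rec["p_lv"][k * n_cyc + es_off]))
        for k in range(n_kept)
    ]
    edv_per_beat = [float(rec["v"][k * n_cyc]) for k in range(n_kept)]
    ees_true = float(rec["e"][es_off])

    rng = np.random.default_rng(seed)
    p_lv = rec["p_lv"] + rng.normal(0.0, noise_pressure, n_rec)
    p_ao = rec["p_ao"] + rng.normal(0.0, noise_pressure, n_rec)
    v_raw = alpha_true * (rec["v"] + Vc_true) + rng.normal(0.0, noise_volume, n_rec)
    truth = GeneratorTruth(
        v_true=rec["v"].copy(), alpha_true=alpha_true, Vc_true=Vc_true,
        V0_true=preset.V0_true, Ees_true=ees_true,
        extras={
            "hr_actual": hr_actual, "n_cycle_samples": n_cyc, "truncated": truncated,
            "es_points": es_points, "edv_per_beat": edv_per_beat,
            "kind": "ivc_occlusion",
        },
    )
    return SignalTrace(t=np.arange(n_rec) / fs, p_lv=p_lv, v=v_raw, p_ao=p_ao,
                       fs=fs, truth=truth)


def simulate_saline_bolus(
    preset: StagePreset,
    Vc_true: float = DEFAULT_VC_TRUE,
    bolus_span: int = 12,
    seed: int = 0,
    *,
    fs: float = DEFAULT_FS,
    noise_pressure: float = DEFAULT_NOISE_PRESSURE,
    noise_volume: float = DEFAULT_NOISE_VOLUME,
    alpha_true: float = DEFAULT_ALPHA_TRUE,
    pre_beats: int = 4,
    post_beats: int = 6,
    s_max: float = 0.40,
    settle_cycles: int = 20,
) -> SignalTrace:
    """Hypertonic-saline transient on the conductance channel.

    Blood conductivity gains a per-beat factor (1 + s_k): zero before the
    bolus, rising linearly to ``s_max`` over ``bolus_span`` wash-in beats,
    then decaying.  True volumes are unchanged, so noise-free per-beat
    (EDV_raw, ESV_raw) pairs drift along an exact line whose intersection
    with the identity recovers ``alpha_true * Vc_true``.
    """
    if bolus_span < 5:
        raise InsufficientDataError("bolus_span must be >= 5 beats")
    n_cyc, t_cycle, hr_actual = _snap_cycle(preset.HR, fs)
    n_beats = pre_beats + bolus_span + post_beats + 1
    n_rec = n_beats * n_cyc
    n_settle = settle_cycles * n_cyc
    pven = np.full(n_settle + n_rec, preset.venous_pressure)
    out = _run(preset, n_settle + n_rec, fs, t_cycle, pven)
    rec = {k: out[k][n_settle:] for k in ("v", "p_lv", "p_ao", "e")}

    s_per_beat = np.zeros(n_beats)
    for j in range(bolus_span):
        s_per_beat[pre_beats + j] = s_max * (j + 1) / bolus_span
    for j in range(post_beats + 1):
        s_per_beat[pre_beats + bolus_span + j] = s_max * np.exp(-(j + 1) / 2.0)
    s = np.repeat(s_per_beat, n_cyc)

    rng = np.random.default_rng(seed)
    p_lv = rec["p_lv"] + rng.normal(0.0, noise_pressure, n_rec)
    p_ao = rec["p_ao"] + rng.normal(0.0, noise_pressure, n_rec)
    v_raw = alpha_true * ((1.0 + s) * rec["v"] + Vc_true) \
        + rng.normal(0.0, noise_volume, n_rec)
    truth = GeneratorTruth(
        v_true=rec["v"].copy(), alpha_true=alpha_true, Vc_true=Vc_true,
        V0_true=preset.V0_true, Ees_true=float(rec["e"].max()),
        extras={
            "hr_actual": hr_actual, "n_cycle_samples": n_cyc,
            "s_per_beat": s_per_beat.tolist(), "pre_beats": pre_beats,
            "bolus_span": bolus_span, "kind": "saline_bolus",
            # stroke volume an independent reference (thermodilution-style)
            # measurement would report for the pre-bolus steady state
            "reference_sv_ml": float(rec["v"][:n_cyc].max() - rec["v"][:n_cyc].min()),
        },
    )
    return SignalTrace(t=np.arange(n_rec) / fs, p_lv=p_lv, v=v_raw, p_ao=p_ao,
                       fs=fs, truth=truth)


def sample_blood_gas(
    preset: StagePreset,
    CO: float,
    seed: int | None = None,
    *,
    noise_sat: float = 1.5,
    noise_lactate: float = 0.12,
    noise_hb: float = 0.1,
    lactate_base: float = 1.4,
    do2_crit: float = 400.0,
    lactate_slope: float = 0.004,
) -> dict:
    """Fick-balance blood-gas panel for a given total cardiac output (L/min).

    SvO2 = SaO2 - 100 * VO2 / (1.34 * 16.114 * Hb * CO), clamped to [0, 100];
    organ venous saturations use the organ VO2 and flow fractions; arterial
    lactate rises linearly once oxygen delivery falls below ``do2_crit``
    (mL O2/min).  ``seed=None`` gives the noise-free panel.
    """
    if CO <= 0:
        raise ValueError("CO must be positive")
    if preset.Hb <= 0:
        raise InvalidPresetError("Hb must be positive")
    cap = O2_PER_HB * preset.Hb * CO  # mL O2/min at 100% saturation
    svo2 = preset.SaO2 - 100.0 * preset.VO2 / cap
    panel = {"SaO2": preset.SaO2, "DO2": cap * preset.SaO2 / 100.0}
    organ = {}
    for name in ("renal", "cerebral"):
        f_v = preset.organ_VO2_fraction[name]
        f_q = preset.organ_flow_fraction[name]
        organ[name] = preset.SaO2 - 100.0 * preset.VO2 * f_v / (cap * f_q)
    lact = lactate_base + lactate_slope * max(0.0, do2_crit - panel["DO2"])
    hb = preset.Hb
    if seed is not None:
        rng = np.random.default_rng(seed)
        svo2 += rng.normal(0.0, noise_sat)
        organ = {k: v + rng.normal(0.0, noise_sat) for k, v in organ.items()}
        lact = max(0.0, lact + rng.normal(0.0, noise_lactate))
        hb = max(0.5, hb + rng.normal(0.0, noise_hb))
    panel.update({
        "SvO2": float(np.clip(svo2, 0.0, 100.0)),
        "renal_vO2": float(np.clip(organ["renal"], 0.0, 100.0)),
        "cerebral_vO2": float(np.clip(organ["cerebral"], 0.0, 100.0)),
        "arterial_lactate": float(lact),
        "venous_lactate": float(lact + 0.1),
        "Hb": float(hb),
    })
    return panel


def stage_truth(preset: StagePreset, fs: float = DEFAULT_FS,
                settle_cycles: int = 18) -> dict:
    """Noise-free stage summary (fast path used by shock induction and cohorts)."""
    n_cyc, t_cycle, hr_actual = _snap_cycle(preset.HR, fs)
    n_total = (settle_cycles + 1) * n_cyc
    pven = np.full(n_total, preset.venous_pressure)
    out = _run(preset, n_total, fs, t_cycle, pven)
    sl = slice(settle_cycles * n_cyc, n_total)
    rec = {k: out[k][sl] for k in ("v", "p_lv", "p_ao", "q_av", "q_pump", "e")}
    return _cycle_truth(preset, rec, slice(0, n_cyc), t_cycle, hr_actual)


def emulate_shock_induction(
    baseline: StagePreset,
    step_fraction: float,
    max_steps: int = 100,
    bsa_m2: float = BSA_M2,
) -> tuple[StagePreset, int]:
    """Stepwise contractility reduction until the shock criterion is met.

    Each step multiplies Emax by (1 - step_fraction), mimicking repeated
    coronary microembolization; after each step SvO2 and cardiac index are
    recomputed and the procedure stops at the first step satisfying
    SvO2 < 30%, SvO2 <= 50% of its baseline value, or CI < 1.5 L/min/m^2.
    """
    if not (0.0 < step_fraction < 0.5):
        raise ValueError("step_fraction must be in (0, 0.5)")
    base = stage_truth(baseline)
    svo2_base = base["SvO2"]
    preset = baseline
    for n in range(1, max_steps + 1):
        new_emax = preset.Emax * (1.0 - step_fraction)
        if new_emax <= preset.Emin * 1.01:
            raise NonConvergenceError(
                "contractility floor reached before the shock criterion"
            )
        preset = preset.with_(Emax=new_emax)
        tr = stage_truth(preset)
        ci = tr["CO_lmin"] / bsa_m2
        if tr["SvO2"] < 30.0 or tr["SvO2"] <= 0.5 * svo2_base or ci < 1.5:
            return preset, n
    raise NonConvergenceError(f"shock criterion not reached in {max_steps} steps")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

DEFAULT_BETWEEN_PIG_SD = {
    # multiplicative lognormal sigmas
    "Emax": 0.15, "Emin": 0.10, "SVR": 0.12, "venous_pressure": 0.08,
    "Cart": 0.10, "VO2": 0.10, "Hb": 0.06,
    # additive sds
    "HR_bpm": 5.0, "V0_ml": 2.5, "Vc_ml": 8.0,
    # lognormal sigma on the per-pig conductance gain
    "alpha": 0.08,
}

DEFAULT_RECORD_NOISE = {
    # measurement noise of stage summaries (within pig): relative for SW,
    # absolute otherwise
    "SW_rel": 0.05, "LVEDV": 3.0, "LVESV": 3.0, "LVEDP": 1.5, "LVESP": 2.0,
    "HR": 1.5, "MAP": 2.0, "RAP": 1.0, "mPAP": 1.5,
    # blood-gas measurement noise (saturation %, lactate mmol/L, Hb mmol/L)
    "sat": 1.5, "lactate": 0.12, "Hb": 0.1,
}

#: column order of the per-pig-stage record frame
RECORD_VARIABLES = [
    "SW", "PE", "PVA", "HR", "cardiac_work", "cardiac_work_e3", "Ees", "Ea",
    "Ea_over_Ees", "LVEDV", "LVEDP", "LVESV", "LVESP", "stroke_volume",
    "MAP", "RAP", "mPAP", "SvO2", "renal_vO2", "cerebral_vO2",
    "arterial_lactate", "venous_lactate", "Hb",
]


def perturb_preset(preset: StagePreset, draws: dict) -> StagePreset:
    """Apply one pig's random parameter draws to a stage preset."""
    return preset.with_(
        Emax=preset.Emax * draws["Emax"],
        Emin=preset.Emin * draws["Emin"],
        SVR=preset.SVR * draws["SVR"],
        venous_pressure=preset.venous_pressure * draws["venous_pressure"],
        Cart=preset.Cart * draws["Cart"],
        VO2=preset.VO2 * draws["VO2"],
        Hb=preset.Hb * draws["Hb"],
        HR=float(np.clip(preset.HR + draws["HR_bpm"], 40.0, 200.0)),
        V0_true=max(2.0, preset.V0_true + draws["V0_ml"]),
    )


def draw_pig_parameters(rng: np.random.Generator,
                        between_pig_sd: dict) -> dict:
    sd = between_pig_sd
    draws = {k: float(np.exp(rng.normal(0.0, sd[k])))
             for k in ("Emax", "Emin", "SVR", "venous_pressure", "Cart", "VO2", "Hb")}
    draws["HR_bpm"] = float(rng.normal(0.0, sd["HR_bpm"]))
    draws["V0_ml"] = float(rng.normal(0.0, sd["V0_ml"]))
    draws["alpha"] = float(DEFAULT_ALPHA_TRUE * np.exp(rng.normal(0.0, sd["alpha"])))
    draws["Vc"] = float(max(5.0, DEFAULT_VC_TRUE + rng.normal(0.0, sd["Vc_ml"])))
    return draws


def _noisy_record(truth: dict, v0: float, rng: np.random.Generator,
                  noise: dict, gas_seed: int, preset: StagePreset) -> dict:
    """Stage summary = truth + measurement noise, derived fields recomputed
    from the noised primitives so internal identities hold."""
    n = noise
    sw = max(0.0, truth["SW"] * (1.0 + rng.normal(0.0, n["SW_rel"])))
    edv = truth["LVEDV"] + rng.normal(0.0, n["LVEDV"])
    esv = truth["LVESV"] + rng.normal(0.0, n["LVESV"])
    esv = min(esv, edv - 2.0)          # ejecting-beat ordering guard
    esv = max(esv, v0 + 2.0)           # keep LVESV above V0
    edp = truth["LVEDP"] + rng.normal(0.0, n["LVEDP"])
    esp = truth["LVESP"] + rng.normal(0.0, n["LVESP"])
    hr = truth["HR"] + rng.normal(0.0, n["HR"])
    pe = esp * (esv - v0) / 2.0
    pva = sw + pe
    gas = sample_blood_gas(preset, truth["CO_lmin"], seed=gas_seed,
                           noise_sat=n["sat"], noise_lactate=n["lactate"],
                           noise_hb=n["Hb"])
    rec = {
        "SW": sw, "PE": pe, "PVA": pva, "HR": hr,
        "cardiac_work": hr * pva, "cardiac_work_e3": hr * pva / 1e3,
        "Ees": esp / (esv - v0), "Ea": esp / max(edv - esv, 1.0),
        "LVEDV": edv, "LVEDP": edp, "LVESV": esv, "LVESP": esp,
        "stroke_volume": edv - esv,
        "MAP": truth["MAP"] + rng.normal(0.0, n["MAP"]),
        "RAP": truth["RAP"] + rng.normal(0.0, n["RAP"]),
        "mPAP": truth["mPAP"] + rng.normal(0.0, n["mPAP"]),
    }
    rec["Ea_over_Ees"] = rec["Ea"] / rec["Ees"]
    rec.update({k: gas[k] for k in
                ("SvO2", "renal_vO2", "cerebral_vO2", "arterial_lactate",
                 "venous_lactate", "Hb")})
    return rec


def simulate_cohort(
    n_pigs: int = 10,
    presets: dict[str, StagePreset] | None = None,
    between_pig_sd: dict | None = None,
    seed: int = 0,
    *,
    level: str = "summary",
    fs: float = DEFAULT_FS,
    duration: float = 30.0,
    record_noise: dict | None = None,
    noise_pressure: float = DEFAULT_NOISE_PRESSURE,
    noise_volume: float = DEFAULT_NOISE_VOLUME,
) -> CohortDataset:
    """Simulate a full crossover cohort.

    Per pig: random parameter draws applied to every stage preset, a random
    permutation of the three blinded catecholamines (phenylephrine fixed
    last), and one record per stage.  ``level='summary'`` produces records
    directly (noise-free ODE truth + record-level measurement noise), the
    fast path for Monte-Carlo work; ``level='trace'`` additionally simulates
    raw traces (stages plus a healthy occlusion run and a saline bolus) for
    the full calibration pipeline.

    Every record row carries the noise-free truth in ``<var>_true`` columns.
    """
    if n_pigs < 2:
        raise InsufficientDataError("n_pigs must be >= 2")
    if level not in ("summary", "trace"):
        raise ValueError("level must be 'summary' or 'trace'")
    presets = presets or default_presets()
    between_pig_sd = {**DEFAULT_BETWEEN_PIG_SD, **(between_pig_sd or {})}
    record_noise = {**DEFAULT_RECORD_NOISE, **(record_noise or {})}

    master = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    stage_order: dict[str, list[str]] = {}
    traces: dict[str, dict] = {}
    presets_by_pig: dict[str, dict[str, StagePreset]] = {}
    for i in range(n_pigs):
        pig = f"pig{i + 1:02d}"
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        draws = draw_pig_parameters(rng, between_pig_sd)
        order = (["baseline", "cs", "impella"]
                 + [BLINDED_DRUG_STAGES[j] for j in rng.permutation(3)]
                 + ["impella_phenyl"])
        stage_order[pig] = order
        pig_presets = {s: perturb_preset(presets[s], draws) for s in STAGE_LABELS}
        presets_by_pig[pig] = pig_presets

        if level == "trace":
            traces[pig] = {
                "occlusion": simulate_ivc_occlusion(
                    pig_presets["baseline"], n_beats=12, preload_decay=0.05,
                    seed=int(rng.integers(0, 2**31 - 1)), fs=fs,
                    noise_pressure=noise_pressure, noise_volume=noise_volume,
                    alpha_true=draws["alpha"], Vc_true=draws["Vc"],
                ),
                "saline": simulate_saline_bolus(
                    pig_presets["baseline"], Vc_true=draws["Vc"],
                    seed=int(rng.integers(0, 2**31 - 1)), fs=fs,
                    noise_pressure=noise_pressure, noise_volume=noise_volume,
                    alpha_true=draws["alpha"],
                ),
            }

        for period, stage in enumerate(order, start=1):
            p = pig_presets[stage]
            if level == "trace":
                tr = simulate_stage(
                    p, duration=duration, fs=fs,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_pressure=noise_pressure, noise_volume=noise_volume,
                    alpha_true=draws["alpha"], Vc_true=draws["Vc"],
                )
                traces[pig][stage] = tr
                truth = tr.truth.stage_means
            else:
                truth = stage_truth(p, fs=fs)
            rec = _noisy_record(
                truth, p.V0_true, rng, record_noise,
                gas_seed=int(rng.integers(0, 2**31 - 1)), preset=p,
            )
            row = {"pig_id": pig, "stage": stage, "period": period}
            row.update({k: rec[k] for k in RECORD_VARIABLES})
            row.update({f"{k}_true": truth[k] for k in RECORD_VARIABLES
                        if k in truth})
            row["valve_open_true"] = truth["valve_open"]
            row["CO_lmin_true"] = truth["CO_lmin"]
            rows.append(row)

    records = pd.DataFrame(rows)
    return CohortDataset(
        pigs=[f"pig{i + 1:02d}" for i in range(n_pigs)],
        stage_order=stage_order, records=records, seed=seed,
        traces=traces or None, presets_by_pig=presets_by_pig,
    )
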