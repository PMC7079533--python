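"""Conductance-catheter calibration.

The raw conductance volume is modelled as an affine transform of true volume,
``v_raw = alpha * (v_true + Vc)``: a dimensionless gain (alpha, anchored to a
reference stroke volume such as thermodilution) and a parallel-conductance
offset (Vc, from the hypertonic-saline wash-in).  The full field-geometry /
blood-conductivity constants of the conductance equation are not separately
identifiable from these data and are absorbed into alpha.  V0 comes from a
caval-occlusion run: the volume-axis intercept of the end-systolic
pressure-volume relationship (ESPVR).

Per-beat ED/ES volume readouts use one fixed within-beat offset (chosen from
the beat-averaged waveform) and a short window mean around it, rather than
per-beat extrema: extrema of a noisy channel are biased outward by several
mL, while a fixed-offset window mean is unbiased and, on noise-free periodic
data, keeps wash-in (EDV, ESV) pairs exactly collinear.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidCalibrationError,
    NonPhysiologicalESPVRError,
)
from .pv_metrics import segment_beats
from .types import SignalTrace


@dataclass
class CalibrationResult:
    """Per-animal calibration constants with fit diagnostics."""

    alpha: float
    Vc: float
    V0: float = 0.0
    Ees_occlusion: float | None = None
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha <= 0:
            raise InvalidCalibrationError(f"alpha must be > 0, got {self.alpha}")
        if self.V0 < 0:
            raise InvalidCalibrationError(f"V0 must be >= 0, got {self.V0}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "alpha": self.alpha, "Vc": self.Vc, "V0": self.V0,
            "Ees_occlusion": self.Ees_occlusion,
            "fit_diagnostics": self.fit_diagnostics,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        return cls(**json.loads(Path(path).read_text()))


def fit_alpha(sv_conductance: float, sv_reference: float) -> float:
    """Gain alpha = conductance-derived SV / reference SV.

    Any independent stroke-volume measurement may anchor the reference; the
    pipeline records which one was used in the result metadata.
    """
    if sv_conductance <= 0 or sv_reference <= 0:
        raise InvalidCalibrationError(
            f"stroke volumes must be positive, got ({sv_conductance}, {sv_reference})"
        )
    return sv_conductance / sv_reference


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < cutoff_hz < nyq):
        return x
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, x)


def beat_volume_readouts(
    v: np.ndarray,
    spans: list[tuple[int, int]],
    fs: float,
    half_window: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat (EDV, ESV) readouts with one fixed within-beat ES offset.

    The ES offset is the argmin of the beat-averaged smoothed volume; EDV is
    the window mean shortly after the beat start (inside the isovolumic
    contraction, where volume still equals EDV), ESV the window mean around
    the shared ES offset (inside the isovolumic relaxation plateau).
    Returns (edv, esv) arrays, one value per span.
    """
    L = min(e - s for s, e in spans)
    margin = max(2, int(0.03 * fs))
    if L < margin + 2 * (2 * half_window + 2):
        raise InsufficientDataError("beats too short for volume readouts")
    vs = _smooth(np.asarray(v, dtype=float), fs, 15.0)
    mean_beat = np.mean([vs[s:s + L] for s, _ in spans], axis=0)
    es_off = int(np.argmin(mean_beat))
    es_off = int(np.clip(es_off, margin + half_window, L - half_window - 1))
    v = np.asarray(v, dtype=float)
    edv = np.array([v[s + margin:s + margin + 2 * half_window + 1].mean()
                    for s, _ in spans])
    esv = np.array([v[s + es_off - half_window:s + es_off + half_window + 1].mean()
                    for s, _ in spans])
    return edv, esv


def estimate_parallel_conductance(
    bolus_trace: SignalTrace,
    alpha: float = 1.0,
    *,
    lowpass_hz: float = 0.5,
    onset_sd: float = 4.0,
) -> tuple[float, dict]:
    """Parallel-conductance volume Vc from a hypertonic-saline wash-in.

    Per-beat (EDV, ESV) pairs in alpha-corrected units drift along a line
    ``ESV = m*EDV + b`` while the bolus washes in; its intersection with the
    identity line, ``Vc = b / (1 - m)``, is the parallel-conductance volume
    in mL.  Wash-in beats lie between bolus onset (the 0.5 Hz low-passed
    volume rising ``onset_sd`` standard deviations above its pre-bolus mean)
    and the low-passed peak.

    Returns (Vc, diagnostics).
    """
    if alpha <= 0:
        raise InvalidCalibrationError("alpha must be positive")
    spans = segment_beats(bolus_trace)
    if len(spans) < 5:
        raise InsufficientDataError("need >= 5 beats in the bolus trace")
    v = np.asarray(bolus_trace.v, dtype=float) / alpha
    v_lp = _smooth(v, bolus_trace.fs, lowpass_hz)

    beat_level = np.array([v_lp[s:e].mean() for s, e in spans])
    base_n = max(2, len(spans) // 4)
    base_mean = beat_level[:base_n].mean()
    base_sd = max(float(beat_level[:base_n].std(ddof=1)), 1e-3)
    above = beat_level > base_mean + onset_sd * base_sd
    if not above.any():
        raise InsufficientDataError("no saline transient detected in volume channel")
    onset = int(np.argmax(above))
    peak = int(np.argmax(beat_level))
    washin = list(range(onset, peak + 1))
    if len(washin) < 5:
        washin = list(range(max(0, onset - (5 - len(washin))), peak + 1))
    if len(washin) < 5:
        raise InsufficientDataError(
            f"only {len(washin)} wash-in beats detected; need >= 5"
        )
    edv_all, esv_all = beat_volume_readouts(v, spans, bolus_trace.fs)
    edv, esv = edv_all[washin], esv_all[washin]
    if np.ptp(edv) < 1e-9:
        raise DegenerateFitError("no spread in wash-in EDV; bolus missing?")
    m, b = np.polyfit(edv, esv, 1)
    if m >= 1.0 - 1e-6:
        raise DegenerateFitError(
            f"wash-in regression slope {m:.6f} is parallel to the identity line"
        )
    vc = float(b / (1.0 - m))
    pred = m * edv + b
    ss_tot = float(np.sum((esv - esv.mean()) ** 2))
    r2 = 1.0 - float(np.sum((esv - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return vc, {"slope": float(m), "intercept": float(b), "r2": r2,
                "n_beats": len(washin), "onset_beat": onset, "peak_beat": peak}


def apply_calibration(trace: SignalTrace, cal: CalibrationResult) -> SignalTrace:
    """Convert raw conductance volumes to mL: ``v_mL = v_raw / alpha - Vc``."""
    if cal.alpha <= 0:
        raise InvalidCalibrationError("alpha must be positive")
    return SignalTrace(
        t=trace.t.copy(), p_lv=trace.p_lv.copy(),
        v=trace.v / cal.alpha - cal.Vc,
        p_ao=trace.p_ao.copy(), fs=trace.fs, truth=trace.truth, calibrated=True,
    )


def estimate_v0_from_occlusion(
    beats: list[tuple[float, float]],
) -> tuple[float, float, dict]:
    """Fit the ESPVR line LVESP = Ees * (LVESV - V0) to occlusion beats.

    ``beats`` are (LVESV mL, LVESP mmHg) pairs from successive beats of a
    preload reduction.  Returns (Ees, V0, diagnostics); V0 is the volume-axis
    intercept, clamped to 0 (with a warning) if a noisy fit puts it negative,
    since the potential-energy and single-beat Ees formulas need V - V0 > 0.
    """
    if len(beats) < 3:
        raise InsufficientDataError("need >= 3 occlusion beats")
    esv = np.array([b[0] for b in beats], dtype=float)
    esp = np.array([b[1] for b in beats], dtype=float)
    if np.ptp(esv) < 1e-9:
        raise DegenerateFitError("all end-systolic volumes identical")
    slope, intercept = np.polyfit(esv, esp, 1)
    if slope <= 0:
        raise NonPhysiologicalESPVRError(
            f"ESPVR slope {slope:.4f} <= 0: pressure must rise with volume"
        )
    v0 = float(-intercept / slope)
    if v0 < 0:
        warnings.warn(f"fitted V0 = {v0:.2f} mL < 0; clamping to 0", stacklevel=2)
        v0 = 0.0
    pred = slope * esv + intercept
    ss_tot = float(np.sum((esp - esp.mean()) ** 2))
    r2 = 1.0 - float(np.sum((esp - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), v0, {"r2": r2, "n_beats": len(beats)}


def espvr_from_trace(trace: SignalTrace, v0_init: float = 0.0,
                     max_iter: int = 10) -> tuple[float, float, dict]:
    """End-systolic points and ESPVR fit from a calibrated occlusion trace.

    ES selection (max P/(V - V0)) depends on V0, so the procedure alternates
    ES detection and line fitting until the selected ES samples stop moving.
    """
    spans = segment_beats(trace)
    if len(spans) < 3:
        raise InsufficientDataError("need >= 3 beats in the occlusion trace")
    v0 = v0_init
    last_idx: list[int] | None = None
    ees, diag = np.nan, {}
    for _ in range(max_iter):
        idx = []
        for s, e in spans:
            denom = trace.v[s:e] - v0
            denom = np.where(denom <= 0.1, np.inf, denom)
            idx.append(s + int(np.argmax(trace.p_lv[s:e] / denom)))
        if idx == last_idx:
            break
        last_idx = idx
        pts = [(float(trace.v[i]), float(trace.p_lv[i])) for i in idx]
        ees, v0, diag = estimate_v0_from_occlusion(pts)
    diag["es_indices"] = last_idx
    return ees, v0, diag


def calibrate_animal(
    saline_trace: SignalTrace,
    occlusion_trace: SignalTrace,
    sv_conductance: float,
    sv_reference: float,
    sv_reference_source: str = "thermodilution",
) -> CalibrationResult:
    """Full per-animal calibration: alpha, Vc, then ESPVR (Ees, V0)."""
    alpha = fit_alpha(sv_conductance, sv_reference)
    vc, vc_diag = estimate_parallel_conductance(saline_trace, alpha=alpha)
    cal0 = CalibrationResult(alpha=alpha, Vc=vc)
    ees, v0, espvr_diag = espvr_from_trace(apply_calibration(occlusion_trace, cal0))
    return CalibrationResult(
        alpha=alpha, Vc=vc, V0=v0, Ees_occlusion=ees,
        fit_diagnostics={
            "saline": vc_diag, "espvr": espvr_diag,
            "sv_reference_source": sv_reference_source,
        },
    )


def conductance_sv(trace: SignalTrace, n_beats: int | None = None) -> float:
    """Mean per-beat stroke volume of the raw conductance channel (raw units)."""
    spans = segment_beats(trace)
    if n_beats is not None:
        spans = spans[:n_beats]
    if not spans:
        raise InsufficientDataError("no beats available for stroke-volume readout")
    edv, esv = beat_volume_readouts(trace.v, spans, trace.fs)
    return float(np.mean(edv - esv))
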