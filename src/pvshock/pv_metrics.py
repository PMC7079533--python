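"""Beat segmentation and pressure-volume loop metrics.

Beats are delimited at end-diastole, detected as the local pressure minimum
immediately preceding each dP/dt upstroke; end-systole is the sample of
maximal instantaneous elastance P/(V - V0), which stays well defined for
pump-supported beats that never open the aortic valve.  Per-beat energies:
stroke work is the shoelace area of the (V, P) loop polygon, potential
energy PE = LVESP * (LVESV - V0) / 2, and PVA = SW + PE (single-beat
construction with a constant V0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateLoopError,
    InsufficientBeatsError,
    InvalidStrokeVolumeError,
    InvalidV0Error,
    NoBeatsError,
    PVShockError,
)
from .types import SignalTrace


@dataclass
class Beat:
    """One cardiac cycle with its landmarks and energies.

    Indices are absolute sample positions into the parent trace; times in
    seconds.  Invariant: PVA = SW + PE exactly.
    """

    start: int
    stop: int
    ed_index: int
    es_index: int
    LVEDV: float
    LVEDP: float
    LVESV: float
    LVESP: float
    SW: float
    PE: float
    PVA: float
    cycle_length: float
    t_start: float
    t_end: float

    @property
    def hr(self) -> float:
        return 60.0 / self.cycle_length


@dataclass
class PVMetrics:
    """Stage-level summary of pressure-volume derived quantities.

    Primitive fields are beat means over the analysis window; derived fields
    (PE, PVA, Ees, Ea, coupling, cardiac work) are recomputed from those
    means so the internal identities hold exactly.
    """

    SW: float
    PE: float
    PVA: float
    HR: float
    cardiac_work: float
    Ees: float
    Ea: float
    Ea_over_Ees: float
    LVEDV: float
    LVEDP: float
    LVESV: float
    LVESP: float
    stroke_volume: float
    n_beats: int
    V0: float


def segment_beats(trace: SignalTrace, rel_threshold: float = 0.3,
                  smooth_hz: float = 15.0, min_cycle_s: float = 0.25,
                  foot_frac: float = 0.1) -> list[tuple[int, int]]:
    """Split a trace into complete cardiac cycles.

    Returns (start, stop) sample spans delimited at end-diastole: each dP/dt
    upstroke crossing of ``rel_threshold * max(dP/dt)`` is traced back to its
    foot (where dP/dt falls below ``foot_frac`` of the threshold) and ED is
    the pressure minimum in a short window ending at that foot — i.e. the
    minimum immediately preceding the upstroke, not the early-diastolic
    global minimum.  Detection runs on a zero-phase low-pass filtered copy of
    the pressure; metric values are read from raw samples.  Incomplete edge
    cycles and spans deviating >25% from the median length are discarded.
    """
    p = np.asarray(trace.p_lv, dtype=float)
    n = len(p)
    if n < 10:
        raise NoBeatsError("trace too short to segment")
    nyq = trace.fs / 2.0
    if 0 < smooth_hz < nyq:
        b, a = butter(4, smooth_hz / nyq)
        ps = filtfilt(b, a, p)
    else:
        ps = p
    dpdt = np.gradient(ps) * trace.fs
    peak = float(np.max(dpdt))
    if peak <= 0 or np.ptp(ps) < 1e-9:
        raise NoBeatsError("no pressure upstrokes detected (flat signal?)")
    thr = rel_threshold * peak
    above = dpdt >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        raise NoBeatsError("no dP/dt upstroke crossings above threshold")
    # enforce a refractory separation between upstrokes
    min_sep = int(min_cycle_s * trace.fs)
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] >= min_sep:
            kept.append(int(c))
    # ED: pressure minimum in a short window ending at the upstroke foot;
    # if the minimum sits on the window edge (monotone filling, no true
    # local minimum) the foot itself is end-diastole
    w = max(2, int(0.024 * trace.fs))
    foot_thr = foot_frac * thr
    eds = []
    prev = 0
    for c in kept:
        i = c
        while i > prev and dpdt[i - 1] > foot_thr:
            i -= 1
        lo = max(prev, i - w)
        j = int(np.argmin(ps[lo:i + 1])) if i >= lo else 0
        eds.append(lo + j if j > 0 else i)
        prev = c
    eds = sorted(set(eds))
    if len(eds) < 2:
        raise NoBeatsError("fewer than two end-diastolic landmarks found")
    spans = [(eds[i], eds[i + 1]) for i in range(len(eds) - 1)]
    lens = np.array([e - s for s, e in spans], dtype=float)
    med = float(np.median(lens))
    spans = [sp for sp, ln in zip(spans, lens) if abs(ln - med) <= 0.25 * med]
    if not spans:
        raise NoBeatsError("no consistent cardiac cycles found")
    return spans


def detect_ed_es(trace: SignalTrace, span: tuple[int, int], V0: float) -> tuple[int, int]:
    """(ed_index, es_index) for one beat span.

    ED is the span start (pressure-minimum convention); ES maximizes the
    instantaneous elastance P/(V - V0), which needs no ejection.
    """
    start, stop = span
    v = trace.v[start:stop]
    if np.any(v <= V0):
        raise InvalidV0Error(
            f"volume reaches V0={V0} inside beat [{start}, {stop}); "
            "calibration or V0 is inconsistent"
        )
    elas = trace.p_lv[start:stop] / (v - V0)
    return start, start + int(np.argmax(elas))


def stroke_work(v: np.ndarray, p: np.ndarray) -> float:
    """Closed-loop area of the (V, P) polygon by the shoelace formula, >= 0."""
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(np.unique(np.column_stack([v, p]), axis=0)) < 3:
        raise DegenerateLoopError("loop has fewer than 3 distinct vertices")
    return 0.5 * abs(float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1))))


def potential_energy(LVESP: float, LVESV: float, V0: float) -> float:
    """PE = LVESP * (LVESV - V0) / 2 (mmHg*mL)."""
    if LVESV <= V0:
        raise InvalidV0Error(f"LVESV={LVESV} must exceed V0={V0}")
    return LVESP * (LVESV - V0) / 2.0


def pva(SW: float, PE: float) -> float:
    """Pressure-volume area: total mechanical energy per beat, SW + PE."""
    if SW < 0 or PE < 0:
        raise PVShockError("SW and PE must be non-negative")
    return SW + PE


def ees_single_beat(LVESP: float, LVESV: float, V0: float) -> float:
    """Single-beat end-systolic elastance LVESP / (LVESV - V0)."""
    if LVESV <= V0:
        raise InvalidV0Error(f"LVESV={LVESV} must exceed V0={V0}")
    return LVESP / (LVESV - V0)


def arterial_elastance(LVESP: float, LVEDV: float, LVESV: float) -> float:
    """Effective afterload Ea = LVESP / stroke volume."""
    sv = LVEDV - LVESV
    if sv <= 0:
        raise InvalidStrokeVolumeError(f"stroke volume must be positive, got {sv}")
    return LVESP / sv

def coupling_ratio(Ea: float, Ees: float) -> float:
    """Ventriculo-arterial coupling Ea/Ees (~1 efficient, >>1 decoupled)."""
    if Ees <= 0:
        raise PVShockError("Ees must be positive")
    return Ea / Ees

def cardiac_work(HR: float, PVA: float) -> float:
    """Per-minute mechanical energy HR * PVA, (mmHg*mL)/min."""
    if HR <= 0:
        raise PVShockError("HR must be positive")
    if PVA < 0:
        raise PVShockError("PVA must be non-negative")
    return HR * PVA


def make_beat(trace: SignalTrace, span: tuple[int, int], V0: float) -> Beat:
    """Assemble a :class:`Beat` with all landmarks and energies."""
    ed, es = detect_ed_es(trace, span, V0)
    start, stop = span
    v = trace.v[start:stop]
    p = trace.p_lv[start:stop]
    sw = stroke_work(v, p)
    pe = potential_energy(float(trace.p_lv[es]), float(trace.v[es]), V0)
    return Beat(
        start=start, stop=stop, ed_index=ed, es_index=es,
        LVEDV=float(trace.v[ed]), LVEDP=float(trace.p_lv[ed]),
        LVESV=float(trace.v[es]), LVESP=float(trace.p_lv[es]),
        SW=sw, PE=pe, PVA=sw + pe,
        cycle_length=(stop - start) / trace.fs,
        t_start=float(trace.t[start]), t_end=float(trace.t[stop - 1]),
    )


def beats_from_trace(trace: SignalTrace, V0: float) -> list[Beat]:
    """Segment a calibrated trace and build every complete beat."""
    return [make_beat(trace, span, V0) for span in segment_beats(trace)]


def summarize_stage(beats: list[Beat], V0: float, window: float = 10.0) -> PVMetrics:
    """Average per-beat quantities over the final ``window`` seconds.

    Primitives (volumes, pressures, SW, cycle length) are averaged; derived
    quantities are recomputed from the averages, so PVA = SW + PE,
    cardiac_work = HR * PVA and Ea/Ees hold exactly in the summary.
    """
    if not beats:
        raise InsufficientBeatsError("no beats supplied")
    t_end = max(b.t_end for b in beats)
    sel = [b for b in beats if b.t_end >= t_end - window]
    if len(sel) < 3:
        raise InsufficientBeatsError(
            f"need >= 3 beats in the final {window}s window, got {len(sel)}"
        )
    mean = lambda f: float(np.mean([getattr(b, f) for b in sel]))
    sw = mean("SW")
    edv, edp = mean("LVEDV"), mean("LVEDP")
    esv, esp = mean("LVESV"), mean("LVESP")
    hr = 60.0 / mean("cycle_length")
    pe = potential_energy(esp, esv, V0)
    total = pva(sw, pe)
    ees = ees_single_beat(esp, esv, V0)
    ea = arterial_elastance(esp, edv, esv)
    return PVMetrics(
        SW=sw, PE=pe, PVA=total, HR=hr, cardiac_work=cardiac_work(hr, total),
        Ees=ees, Ea=ea, Ea_over_Ees=coupling_ratio(ea, ees),
        LVEDV=edv, LVEDP=edp, LVESV=esv, LVESP=esp,
        stroke_volume=edv - esv, n_beats=len(sel), V0=V0,
    )
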