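"""Lumped-parameter hemodynamic engine.

One ventricle (time-varying elastance), a two-element Windkessel afterload,
a diode mitral inflow from a constant-pressure venous source, a diode aortic
valve, and a continuous axial-flow pump from ventricle to aorta with a linear
head-flow characteristic.  The state is (V_lv, P_ao) and the pressure law is

    P_lv(t) = E(t) * (V_lv - V0),      E(t) = Emin + (Emax - Emin) * phi(t/T)

where phi is the double-Hill activation normalized to peak 1.  Integration is
explicit Euler on a fine internal grid (a fixed number of substeps per output
sample), jitted with numba; every run is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

# Double-Hill activation shape constants (dimensionless; time constants are
# fractions of the cycle length, so the normalization constant is universal).
_N1 = 1.9
_N2 = 21.9
_TAU1 = 0.269
_TAU2 = 0.452


@njit(cache=True)
def _phi_raw(s: float) -> float:
    """Unnormalized double-Hill activation at cycle fraction s in [0, 1)."""
    a = (s / _TAU1) ** _N1
    b = (s / _TAU2) ** _N2
    return (a / (1.0 + a)) / (1.0 + b)


def _compute_phi_max() -> float:
    res = minimize_scalar(
        lambda s: -_phi_raw(s), bounds=(0.05, 0.95), method="bounded",
        options={"xatol": 1e-14},
    )
    return float(-res.fun)


PHI_MAX = _compute_phi_max()


def activation(s):
    """Normalized activation (peak exactly 1 at the double-Hill argmax).

    Parameters
    ----------
    s : float or ndarray
        Cycle fraction(s), values taken modulo 1.
    """
    s = np.asarray(s, dtype=float) % 1.0
    a = (s / _TAU1) ** _N1
    b = (s / _TAU2) ** _N2
    return ((a / (1.0 + a)) / (1.0 + b)) / PHI_MAX


@njit(cache=True)
def _integrate(
    n_out: int,
    substeps: int,
    dt: float,
    t_cycle: float,
    emax: float,
    emin: float,
    v0: float,
    r_mv: float,
    r_av: float,
    svr: float,
    cart: float,
    rap: float,
    pven: np.ndarray,       # venous filling pressure per *output* sample
    q_pump_max: float,      # mL/s at the commanded level
    pump_k: float,          # mL/s per mmHg of head
    phi_max: float,
    v_init: float,
    pao_init: float,
    out_v: np.ndarray,
    out_plv: np.ndarray,
    out_pao: np.ndarray,
    out_qav: np.ndarray,
    out_qpump: np.ndarray,
    out_e: np.ndarray,
) -> int:
    """Fill output arrays sampled every `substeps` internal steps.

    Returns -1 on success, or the output-sample index at which the state
    diverged (non-finite or wildly out of range volumes).
    """
    v = v_init
    pao = pao_init
    t = 0.0
    for i in range(n_out):
        # record at the top of each output sample
        s = (t % t_cycle) / t_cycle
        a = (s / _TAU1) ** _N1
        b = (s / _TAU2) ** _N2
        e = emin + (emax - emin) * ((a / (1.0 + a)) / (1.0 + b)) / phi_max
        plv = e * (v - v0)
        head = pao - plv
        qp = q_pump_max - pump_k * head
        if qp < 0.0:
            qp = 0.0
        elif qp > q_pump_max:
            qp = q_pump_max
        qav = (plv - pao) / r_av if plv > pao else 0.0
        out_v[i] = v
        out_plv[i] = plv
        out_pao[i] = pao
        out_qav[i] = qav
        out_qpump[i] = qp
        out_e[i] = e
        pv = pven[i]
        for _ in range(substeps):
            s = (t % t_cycle) / t_cycle
            a = (s / _TAU1) ** _N1
            b = (s / _TAU2) ** _N2
            e = emin + (emax - emin) * ((a / (1.0 + a)) / (1.0 + b)) / phi_max
            plv = e * (v - v0)
            qmv = (pv - plv) / r_mv if pv > plv else 0.0
            qav = (plv - pao) / r_av if plv > pao else 0.0
            head = pao - plv
            qp = q_pump_max - pump_k * head
            if qp < 0.0:
                qp = 0.0
            elif qp > q_pump_max:
                qp = q_pump_max
            v += dt * (qmv - qav - qp)
            pao += dt * (qav + qp - (pao - rap) / svr) / cart
            t += dt
        if not (np.isfinite(v) and np.isfinite(pao)) or v > 2000.0 or v < -100.0:
            return i
    return -1


def integrate_stage(
    *,
    n_out: int,
    fs: float,
    t_cycle: float,
    emax: float,
    emin: float,
    v0: float,
    r_mv: float,
    r_av: float,
    svr: float,
    cart: float,
    rap: float,
    pven: np.ndarray,
    q_pump_max_mls: float,
    pump_k_mls_per_mmhg: float,
    v_init: float,
    pao_init: float,
    substeps: int = 8,
) -> dict:
    """Run the Euler integration and return channel arrays at the output rate.

    `pven` must have length `n_out` (venous pressure may step between beats,
    e.g. during a caval occlusion).  Raises no errors itself; the caller maps
    a non-negative failure index to a simulation-failure error.
    """
    dt = 1.0 / (fs * substeps)
    out = {k: np.empty(n_out) for k in ("v", "p_lv", "p_ao", "q_av", "q_pump", "e")}
    fail = _integrate(
        n_out, substeps, dt, t_cycle, emax, emin, v0, r_mv, r_av, svr, cart,
        rap, np.ascontiguousarray(pven, dtype=np.float64),
        q_pump_max_mls, pump_k_mls_per_mmhg, PHI_MAX, v_init, pao_init,
        out["v"], out["p_lv"], out["p_ao"], out["q_av"], out["q_pump"], out["e"],
    )
    out["fail_index"] = fail
    return out
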