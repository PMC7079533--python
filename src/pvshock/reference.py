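"""Published stage-level reference values the synthetic presets are calibrated to.

These are group means (with 95% CIs) from the porcine profound-cardiogenic-shock
experiment that this analysis emulates: ten ~70 kg pigs, shock induced by coronary
microsphere embolization, supported by a transvalvular axial-flow pump (max 3.5 L/min),
then a blinded crossover of equipotent catecholamine infusions and a final
phenylephrine infusion.  The synthetic-data generator treats these numbers as
calibration targets; the mixed-model contrasts (drug stage minus pump-alone
reference) give the sign pattern the generator's drug presets must reproduce.

Units follow the source: energies in mmHg*mL, cardiac work in (mmHg*mL)/min,
pressures in mmHg, volumes in mL, saturations in %, lactate and hemoglobin in mmol/L.
"""

from __future__ import annotations

# Stage-level means, columns: baseline / cardiogenic shock / 30 min of pump support.
# value = mean, ci = (lower, upper) 95% CI.
TABLE1: dict[str, dict[str, dict]] = {
    "SW": {
        "baseline": {"mean": 4853.0, "ci": (3906.0, 5801.0)},
        "cs": {"mean": 703.0, "ci": (350.0, 1056.0)},
        "impella": {"mean": 980.0, "ci": (619.0, 1340.0)},
    },
    "PE": {
        "baseline": {"mean": 4290.0, "ci": (2887.0, 5694.0)},
        "cs": {"mean": 4567.0, "ci": (2973.0, 6161.0)},
        "impella": {"mean": 2690.0, "ci": (2019.0, 3361.0)},
    },
    "PVA": {
        "baseline": {"mean": 9143.0, "ci": (7406.0, 10880.0)},
        "cs": {"mean": 5270.0, "ci": (3468.0, 7072.0)},
        "impella": {"mean": 3670.0, "ci": (2780.0, 4560.0)},
    },
    "HR": {
        "baseline": {"mean": 82.0, "ci": (75.0, 89.0)},
        "cs": {"mean": 81.0, "ci": (75.0, 87.0)},
        "impella": {"mean": 75.0, "ci": (69.0, 82.0)},
    },
    # cardiac work = HR x PVA, printed as 10^3 (mmHg*mL)/min
    "cardiac_work_e3": {
        "baseline": {"mean": 751.7, "ci": (595.2, 906.1)},
        "cs": {"mean": 430.3, "ci": (271.3, 589.2)},
        "impella": {"mean": 274.2, "ci": (206.9, 341.5)},
    },
    "Ees": {
        "baseline": {"mean": 1.42, "ci": (1.06, 1.79)},
        "cs": {"mean": 0.40, "ci": (0.3, 0.5)},
        "impella": {"mean": 0.74, "ci": (0.57, 0.92)},
    },
    "LVEDV": {
        "baseline": {"mean": 156.1, "ci": (133.0, 179.0)},
        "cs": {"mean": 188.8, "ci": (154.0, 224.0)},
        "impella": {"mean": 125.2, "ci": (108.0, 142.0)},
    },
    "LVEDP": {
        "baseline": {"mean": 16.0, "ci": (12.7, 19.2)},
        "cs": {"mean": 22.0, "ci": (19.7, 24.8)},
        "impella": {"mean": 19.0, "ci": (15.0, 22.0)},
    },
    "LVESV": {
        "baseline": {"mean": 91.1, "ci": (69.0, 113.2)},
        "cs": {"mean": 162.7, "ci": (130.2, 195.2)},
        "impella": {"mean": 97.0, "ci": (82.4, 111.5)},
    },
    "LVESP": {
        "baseline": {"mean": 104.87, "ci": (91.4, 118.3)},
        "cs": {"mean": 58.35, "ci": (48.8, 67.9)},
        "impella": {"mean": 61.65, "ci": (50.5, 72.9)},
    },
    "MAP": {
        "baseline": {"mean": 79.0, "ci": (71.0, 88.0)},
        "cs": {"mean": 39.0, "ci": (30.0, 48.0)},
        "impella": {"mean": 61.0, "ci": (51.0, 72.0)},
    },
    "RAP": {
        "baseline": {"mean": 9.0, "ci": (7.0, 11.0)},
        "cs": {"mean": 14.0, "ci": (10.0, 17.0)},
        "impella": {"mean": 12.0, "ci": (9.0, 14.0)},
    },
    "mPAP": {
        "baseline": {"mean": 21.0, "ci": (19.0, 24.0)},
        "cs": {"mean": 25.0, "ci": (21.0, 29.0)},
        "impella": {"mean": 24.0, "ci": (20.0, 28.0)},
    },
    "arterial_lactate": {
        "baseline": {"mean": 1.49, "ci": (1.05, 1.94)},
        "cs": {"mean": 2.1, "ci": (1.67, 2.51)},
        "impella": {"mean": 2.22, "ci": (1.65, 2.79)},
    },
    "SvO2": {
        "baseline": {"mean": 76.0, "ci": (69.0, 82.0)},
        "cs": {"mean": 37.0, "ci": (30.0, 44.0)},
        "impella": {"mean": 55.0, "ci": (47.0, 64.0)},
    },
    "renal_vO2": {
        "baseline": {"mean": 89.0, "ci": (85.0, 92.0)},
        "cs": {"mean": 58.0, "ci": (42.0, 75.0)},
        "impella": {"mean": 73.0, "ci": (62.0, 85.0)},
    },
    "cerebral_vO2": {
        "baseline": {"mean": 79.0, "ci": (73.0, 85.0)},
        "cs": {"mean": 45.0, "ci": (35.0, 55.0)},
        "impella": {"mean": 59.0, "ci": (48.0, 71.0)},
    },
    "Hb": {
        "baseline": {"mean": 6.4, "ci": (5.7, 7.1)},
        "cs": {"mean": 5.6, "ci": (5.1, 6.2)},
        "impella": {"mean": 6.1, "ci": (5.6, 6.6)},
    },
}

# Crossover mixed-model contrasts: mean difference from the pump-alone reference
# stage, as (mean, ci_lo, ci_hi, p).  Only the sign pattern is used for generator
# calibration; magnitudes provide a sanity scale.
TABLE2: dict[str, dict[str, tuple]] = {
    "SW": {
        "impella_epi": (1175.0, 279.0, 2070.0, 0.01),
        "impella_dopa": (1974.0, 1111.0, 2838.0, 1e-4),
        "impella_nor": (1086.0, 260.0, 1912.0, 0.01),
        "impella_phenyl": (604.0, -116.0, 1324.0, 0.1),
    },
    "PE": {
        "impella_epi": (324.0, -1016.0, 1664.0, 0.636),
        "impella_dopa": (-53.0, -1346.0, 1239.0, 0.936),
        "impella_nor": (929.0, -306.0, 2165.0, 0.140),
        "impella_phenyl": (2220.0, 1142.0, 3298.0, 1e-4),
    },
    "PVA": {
        "impella_epi": (1506.0, 121.0, 2890.0, 0.033),
        "impella_dopa": (1928.0, 593.0, 3263.0, 0.005),
        "impella_nor": (2023.0, 746.0, 3299.0, 0.002),
        "impella_phenyl": (2824.0, 1711.0, 3938.0, 1e-4),
    },
    "HR": {
        "impella_epi": (15.0, 3.0, 28.0, 0.016),
        "impella_dopa": (29.0, 17.0, 41.0, 1e-4),
        "impella_nor": (3.0, -8.0, 15.0, 0.554),
        "impella_phenyl": (32.0, 22.0, 42.0, 1e-4),
    },
    "cardiac_work_e3": {
        "impella_epi": (202.2, 28.3, 376.1, 0.023),
        "impella_dopa": (341.8, 174.1, 509.5, 1e-4),
        "impella_nor": (186.3, 26.0, 346.6, 0.023),
        "impella_phenyl": (437.8, 297.9, 577.6, 1e-4),
    },
    "SvO2": {
        # only phenylephrine printed numerically (-9%, CI -19..0, p=0.063);
        # catecholamine SvO2 rose significantly (sign only).
        "impella_phenyl": (-9.0, -19.0, 0.0, 0.063),
    },
}

# Maximum pump output of the axial-flow device, L/min.
PUMP_QMAX_LMIN = 3.5

# Constant unstressed volume implied by the printed Ees / LVESP / LVESV triplets
# (both baseline and shock columns give ~17 mL).
V0_REFERENCE_ML = 17.0
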