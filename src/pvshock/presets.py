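"""Stage presets: the generator's parameterization of each experimental condition.

Seven stages per pig: healthy baseline, onset of cardiogenic shock (CS),
30 min of axial-flow pump support, three blinded catecholamine infusions in
randomized order on top of the pump, and a final phenylephrine infusion.

The numbers below were calibrated once against the published stage means of the
porcine experiment (see :mod:`pvshock.reference`): contractility (Emax) and
diastolic stiffness (Emin) reproduce the printed Ees / LVESP / LVESV / LVEDP
triplets with a constant V0 = 17 mL; systemic resistance, compliance and venous
filling pressure reproduce MAP, RAP and the stage flows implied by the Fick
oxygen balance; drug presets are phenomenological parameter shifts whose signs
reproduce the crossover contrast table (catecholamines: contractility and HR up;
norepinephrine: mostly resistance, HR unchanged; phenylephrine: resistance and
HR up with no inotropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidPresetError
from .reference import PUMP_QMAX_LMIN, V0_REFERENCE_ML

STAGE_LABELS = (
    "baseline",
    "cs",
    "impella",
    "impella_epi",
    "impella_dopa",
    "impella_nor",
    "impella_phenyl",
)

#: the three blinded infusions whose order is randomized per pig
BLINDED_DRUG_STAGES = ("impella_epi", "impella_dopa", "impella_nor")

#: equipotent doses each drug preset encodes (information only; effects are
#: phenomenological parameter shifts, not pharmacokinetics)
DRUG_DOSES = {
    "impella_epi": "epinephrine 0.10 ug/kg/min",
    "impella_dopa": "dopamine 10 ug/kg/min",
    "impella_nor": "norepinephrine 0.10 ug/kg/min",
    "impella_phenyl": "phenylephrine 10 ug/kg/min",
}


@dataclass(frozen=True)
class StagePreset:
    """Generator parameter set for one experimental condition.

    Units: elastances mmHg/mL, volumes mL, HR bpm, resistances mmHg*s/mL,
    compliance mL/mmHg, pressures mmHg, VO2 mL O2/min, Hb mmol/L.
    """

    stage_label: str
    Emax: float
    Emin: float
    V0_true: float
    HR: float
    SVR: float
    Cart: float
    venous_pressure: float
    pump_level: float
    VO2: float
    organ_VO2_fraction: dict = field(
        default_factory=lambda: {"renal": 0.07, "cerebral": 0.105}
    )
    Hb: float = 6.4
    # fixed-offset right-heart / pulmonary surrogates and valve resistances
    rap: float = 9.0
    mpap: float = 21.0
    SaO2: float = 98.0
    organ_flow_fraction: dict = field(
        default_factory=lambda: {"renal": 0.20, "cerebral": 0.12}
    )
    R_mv: float = 0.03
    R_av: float = 0.04
    pump_qmax_lmin: float = PUMP_QMAX_LMIN
    pump_k_lmin_per_mmhg: float = 0.02

    def __post_init__(self):
        if self.stage_label not in STAGE_LABELS:
            raise InvalidPresetError(f"unknown stage label {self.stage_label!r}")
        if not (self.Emax > self.Emin > 0):
            raise InvalidPresetError(
                f"need Emax > Emin > 0, got Emax={self.Emax}, Emin={self.Emin}"
            )
        if not (0.0 <= self.pump_level <= 1.0):
            raise InvalidPresetError(f"pump_level must be in [0, 1], got {self.pump_level}")
        if not (30.0 <= self.HR <= 220.0):
            raise InvalidPresetError(f"HR must be in [30, 220] bpm, got {self.HR}")
        for name in ("SVR", "Cart", "R_mv", "R_av"):
            if getattr(self, name) <= 0:
                raise InvalidPresetError(f"{name} must be > 0")
        if self.V0_true < 0 or self.VO2 < 0 or self.Hb <= 0:
            raise InvalidPresetError("V0_true, VO2 must be >= 0 and Hb > 0")

    def with_(self, **kwargs) -> "StagePreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_presets() -> dict[str, StagePreset]:
    """The calibrated per-stage presets (the study conditions)."""
    base = StagePreset(
        stage_label="baseline",
        Emax=1.43, Emin=0.118, V0_true=V0_REFERENCE_ML,
        HR=82.0, SVR=0.93, Cart=1.4, venous_pressure=17.5,
        pump_level=0.0, VO2=160.0, Hb=6.4, rap=9.0, mpap=21.0,
        pump_k_lmin_per_mmhg=0.02,
    )
    cs = base.with_(
        stage_label="cs",
        Emax=0.36, Emin=0.132, HR=81.0, SVR=0.90, Cart=1.6,
        venous_pressure=24.5, Hb=5.6, rap=14.0, mpap=25.0,
    )
    impella = cs.with_(
        stage_label="impella",
        Emax=0.74, Emin=0.175, HR=75.0, SVR=0.90, Cart=0.95,
        venous_pressure=19.0, pump_level=1.0, Hb=6.1, rap=12.0, mpap=24.0,
    )
    epi = impella.with_(
        stage_label="impella_epi",
        Emax=1.10, HR=90.0, SVR=0.95, venous_pressure=19.5,
        Hb=6.7, rap=10.0, mpap=22.0,
    )
    dopa = impella.with_(
        stage_label="impella_dopa",
        Emax=1.45, HR=104.0, SVR=0.85, venous_pressure=19.5,
        Hb=6.6, rap=9.0, mpap=26.0,
    )
    nor = impella.with_(
        stage_label="impella_nor",
        Emax=1.00, HR=78.0, SVR=1.25, venous_pressure=21.0,
        Hb=6.1, rap=10.0, mpap=25.0,
    )
    phenyl = impella.with_(
        stage_label="impella_phenyl",
        Emax=0.74, HR=107.0, SVR=1.85, Cart=1.0,
        venous_pressure=24.0, Hb=6.9, rap=14.0, mpap=33.0,
    )
    return {p.stage_label: p for p in (base, cs, impella, epi, dopa, nor, phenyl)}
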