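"""Core containers: signal traces, generator truth, cohort datasets."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GeneratorTruth:
    """Ground truth attached to a synthetic trace.

    ``Ees_true`` is the maximum of the sampled elastance waveform — the exact
    slope of the sampled end-systolic points — and ``v_true`` the noise-free
    calibrated volume channel.  ``stage_means`` holds the noise-free value of
    every stage-level summary variable the analysis estimates downstream.
    """

    v_true: np.ndarray
    alpha_true: float
    Vc_true: float
    V0_true: float
    Ees_true: float
    stage_means: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha_true": self.alpha_true,
            "Vc_true": self.Vc_true,
            "V0_true": self.V0_true,
            "Ees_true": self.Ees_true,
            "stage_means": {k: _jsonable(v) for k, v in self.stage_means.items()},
            "extras": {k: _jsonable(v) for k, v in self.extras.items()},
            "v_true": np.asarray(self.v_true).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


@dataclass
class SignalTrace:
    """Synchronized LV pressure / volume / aortic pressure samples.

    ``v`` holds raw conductance units when ``calibrated`` is False and mL
    after :func:`pvshock.calibration.apply_calibration`.
    """

    t: np.ndarray
    p_lv: np.ndarray
    v: np.ndarray
    p_ao: np.ndarray
    fs: float
    truth: GeneratorTruth | None = None
    calibrated: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p_lv = np.asarray(self.p_lv, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.p_ao = np.asarray(self.p_ao, dtype=float)
        n = len(self.t)
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        if not (len(self.p_lv) == len(self.v) == len(self.p_ao) == n):
            raise ValueError("all channels must have the same length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs

    def to_csv(self, path: str | Path, truth_sidecar: str | Path | None = None) -> None:
        """Write ``t,p_lv,v_raw,p_ao`` (or ``v_ml`` once calibrated) rows."""
        vcol = "v_ml" if self.calibrated else "v_raw"
        df = pd.DataFrame({"t": self.t, "p_lv": self.p_lv, vcol: self.v, "p_ao": self.p_ao})
        df.to_csv(path, index=False)
        if truth_sidecar is not None and self.truth is not None:
            self.truth.to_json(truth_sidecar)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalTrace":
        df = pd.read_csv(path)
        vcol = "v_ml" if "v_ml" in df.columns else "v_raw"
        t = df["t"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t=t, p_lv=df["p_lv"].to_numpy(), v=df[vcol].to_numpy(),
            p_ao=df["p_ao"].to_numpy(), fs=fs, calibrated=(vcol == "v_ml"),
        )


@dataclass
class CohortDataset:
    """One simulated crossover experiment.

    ``records`` is a tidy frame with one row per pig x stage carrying every
    summary variable alongside its ``*_true`` noise-free counterpart;
    ``stage_order`` maps each pig to its 7-stage sequence (three blinded
    catecholamines permuted, phenylephrine always last); ``traces`` is only
    populated at trace level and then holds per-pig occlusion, saline-bolus
    and per-stage raw traces.
    """

    pigs: list
    stage_order: dict
    records: pd.DataFrame
    seed: int
    traces: dict | None = None
    presets_by_pig: dict | None = None

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)
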