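import numpy as np
import pytest

from pvshock import calibration as cal
from pvshock import pv_metrics as pv
from pvshock import synthetic_data as sd
from pvshock.presets import default_presets


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def baseline_trace_clean(presets):
    """Noise-free healthy-baseline trace with identity raw-volume transform."""
    return sd.simulate_stage(
        presets["baseline"], duration=20.0, seed=0,
        noise_pressure=0.0, noise_volume=0.0, alpha_true=1.0, Vc_true=0.0,
    )


@pytest.fixture(scope="session")
def baseline_beats_clean(baseline_trace_clean, presets):
    v0 = presets["baseline"].V0_true
    tr = cal.apply_calibration(
        baseline_trace_clean, cal.CalibrationResult(alpha=1.0, Vc=0.0, V0=v0))
    return pv.beats_from_trace(tr, v0), v0


@pytest.fixture(scope="session")
def occlusion_trace_clean(presets):
    return sd.simulate_ivc_occlusion(
        presets["baseline"], n_beats=10, preload_decay=0.05, seed=1,
        noise_pressure=0.0, noise_volume=0.0, alpha_true=1.0, Vc_true=0.0,
    )


@pytest.fixture(scope="session")
def saline_trace_clean(presets):
    return sd.simulate_saline_bolus(
        presets["baseline"], Vc_true=50.0, seed=1,
        noise_pressure=0.0, noise_volume=0.0, alpha_true=1.3,
    )


@pytest.fixture(scope="session")
def summary_cohort():
    return sd.simulate_cohort(n_pigs=6, seed=11, level="summary")


def make_crossover_frame(n_pigs=8, effects=None, pig_sd=2.0, noise_sd=1.0,
                         seed=0, stages=("impella", "drugA", "drugB")):
    """Hand-built balanced crossover records for stats tests."""
    import pandas as pd

    effects = effects or {s: 0.0 for s in stages}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pigs):
        b = rng.normal(0.0, pig_sd)
        for j, s in enumerate(stages):
            rows.append({
                "pig_id": f"p{i:02d}", "stage": s, "period": j + 1,
                "y": 50.0 + b + effects[s] + rng.normal(0.0, noise_sd),
            })
    return pd.DataFrame(rows)
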