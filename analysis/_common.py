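"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from pvshock import synthetic_data as sd

SEED = 42
N_PIGS = 10
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

_cache = {}


def get_cohort():
    """The study cohort (trace level), regenerated deterministically."""
    if "cohort" not in _cache:
        _cache["cohort"] = sd.simulate_cohort(n_pigs=N_PIGS, seed=SEED,
                                              level="trace")
    return _cache["cohort"]
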