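"""Shared configuration for the numbered analysis drivers.

One study condition, one seed: every driver works from the same simulated
tumor dataset (deterministic given the seed), at a scale where the doublet
scorer is well calibrated, and writes its tables under results/.
"""

from pathlib import Path

from orsmell.synthetic_data import SimulationConfig

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(**overrides) -> SimulationConfig:
    kwargs = dict(seed=SEED, n_cells=500, n_background_genes=600,
                  n_or_functional=400, n_or_pseudo=600, n_patients=200)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def out_dir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
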