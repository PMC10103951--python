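"""Shared helpers for the numbered analysis drivers.

The drivers operate on a synthetic dataset generated under the default study
conditions (seed 0).  The dataset is materialized once under ``scratch/`` —
bulky intermediates stay out of the repository — and small summary tables go
to ``results/``.
"""

from pathlib import Path

from braincirc import cli, simulate as sim

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
DATASET_DIR = SCRATCH / "dataset"


def load_or_simulate(seed: int = 0) -> dict:
    RESULTS.mkdir(exist_ok=True)
    cfg = sim.SimConfig(seed=seed)
    data = sim.simulate_dataset(cfg)
    if not (DATASET_DIR / "bsj_counts.tsv").exists():
        cli.write_dataset(cfg, DATASET_DIR)
    return data
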