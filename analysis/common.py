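"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from pescreen.pipeline import simulate_registry
from pescreen.registry import read_registry

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
REGISTRY_CSV = RESULTS / "registry.csv"

#: Analysis problem size: 50,000 pregnancies per parity stratum (the full
#: published stratum sizes are ~344k/283k; this scale keeps every stage
#: interactive while leaving all rates and effect sizes unchanged).
N_PER_STRATUM = 50_000
SEED = 20260924


def load_registry() -> pd.DataFrame:
    """The analysis registry; simulated on first use."""
    RESULTS.mkdir(exist_ok=True)
    if not REGISTRY_CSV.exists():
        simulate_registry(REGISTRY_CSV, n_per_stratum=N_PER_STRATUM, seed=SEED)
    return read_registry(REGISTRY_CSV)
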