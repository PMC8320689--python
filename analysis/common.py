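"""Shared setup for the numbered analysis scripts.

The demonstration cohort is 30 tumor/normal pairs simulated at the
default study conditions (seed 7). Pileups and full call tables are
cached under ``scratch/`` (regenerable, not part of the repository);
every table the analysis reports lands under ``results/cohort/``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mitosoma.caller import call_sample
from mitosoma.reference import load_reference
from mitosoma.simulate import SimulationConfig, simulate_pair

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "cohort"
SCRATCH = ROOT / "scratch" / "cohort_cache"

SEED = 7
N_PAIRS = 30
CONFIG = SimulationConfig(seed=SEED, n_pairs=N_PAIRS)


def load_cohort():
    """Simulated pairs for the demo cohort (deterministic in SEED)."""
    model = load_reference()
    return model, [simulate_pair(CONFIG, i, model=model) for i in range(N_PAIRS)]


def cached_calls(pairs):
    """Per-sample call tables, cached as TSVs under scratch/."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    calls = {}
    for pair in pairs:
        for table in (pair.tumor, pair.normal):
            cache = SCRATCH / f"{table.sample_id}.calls.tsv"
            if cache.exists():
                calls[table.sample_id] = pd.read_csv(
                    cache, sep="\t", dtype={"ref": str, "alt": str, "filters": str}
                )
            else:
                calls[table.sample_id] = call_sample(table)
                calls[table.sample_id].to_csv(cache, sep="\t", index=False)
    return calls


def sample_sheet(pairs) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for role, table in (("tumor", p.tumor), ("normal", p.normal)):
            rows.append(
                {"sample_id": table.sample_id, "subject_id": p.subject_id,
                 "subtype": p.subtype, "role": role, "timepoint": 0}
            )
    return pd.DataFrame(rows)
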