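"""Generate the reference synthetic discharge database.

Emits a one-year stay table, the hospital registry and the true archetype
of each hospital under scratch/reference_run/.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd

from hospiflow.pipeline import stage_simulate

if __name__ == "__main__":
    d = stage_simulate(common.CONFIG)
    stays = pd.read_csv(d / "stays.csv", usecols=["hospital_id"])
    registry = pd.read_csv(d / "registry.csv")
    print(f"generated {len(stays):,} stays across {len(registry)} hospitals "
          f"in {registry['rhg_id'].nunique()} regional groups -> {d}")
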