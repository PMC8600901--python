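"""Shared configuration of the reference analysis run.

All numbered drivers operate on the same run directory under scratch/
(bulky intermediates) and copy their small result tables into results/.
The reference run emulates the 2016 national system at half data volume:
three hospital archetypes (34 reference centers, 236 medium, 157 small
hospitals), volume thresholds scaled jointly with the volumes.
"""

import shutil
from pathlib import Path

from hospiflow.pipeline import reference_pipeline_config

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "reference_run"
RESULTS = ROOT / "results"
SEED = 2016

CONFIG = reference_pipeline_config(run_dir=str(RUN_DIR), seed=SEED, volume_scale=0.5)


def publish(*names: str) -> None:
    """Copy small run artifacts into results/ for the record."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        src = RUN_DIR / name
        dst = RESULTS / Path(name).name
        dst.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(src, dst)
        print(f"  results/{Path(name).name}")
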