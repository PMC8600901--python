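"""Apply the inclusion rules and report what each rule removed."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd

from hospiflow.pipeline import stage_ingest

if __name__ == "__main__":
    d = stage_ingest(common.CONFIG)
    ledger = pd.read_csv(d / "exclusion_ledger.csv")
    kept = pd.read_csv(d / "filtered_stays.csv", usecols=["hospital_id"])
    print(ledger.to_string(index=False))
    print(f"retained {len(kept):,} stays at {kept['hospital_id'].nunique()} hospitals")
    common.publish("exclusion_ledger.csv")
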