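"""Detect inter-hospital mobility and summarize the readmission window."""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd

from hospiflow.mobility import window_profile, within_rhg_share
from hospiflow.pipeline import stage_mobility

if __name__ == "__main__":
    d = stage_mobility(common.CONFIG)
    events = pd.read_csv(d / "events.csv")
    diag = json.loads((d / "mobility_diagnostics.json").read_text())
    print(f"{len(events):,} mobility events from {diag['n_index_stays']:,} stays "
          f"({diag['n_overlap_skipped']} overlapping pairs skipped)")
    prof = window_profile(events)
    print("cumulative share by gap:",
          ", ".join(f"<= {c} d: {v:.1%}" for c, v in prof.items()))
    print(f"within-group share: {within_rhg_share(events):.1%} "
          f"(strong pairs only: {within_rhg_share(events, common.CONFIG.strong_threshold):.1%})")
    common.publish("mobility_diagnostics.json")
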