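"""Choose k by majority rule, fit k-means, and profile the clusters."""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd

from hospiflow.pipeline import stage_cluster

if __name__ == "__main__":
    d = stage_cluster(common.CONFIG)
    ks = json.loads((d / "kselect.json").read_text())
    print(f"index votes: {ks['votes']} -> majority k = {ks['majority_k']}")
    curve = {int(k): v for k, v in ks["wss_curve"].items()}
    drops = {k: curve[k - 1] - curve[k] for k in sorted(curve) if k - 1 in curve}
    print("WSS drop by added cluster:",
          ", ".join(f"k={k}: {v:,.0f}" for k, v in drops.items()))
    prof = pd.read_csv(d / "cluster_profiles.csv", index_col="cluster")
    print(prof.round(2).to_string())
    common.publish("kselect.json", "cluster_profiles.csv", "domain_pct.csv")
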