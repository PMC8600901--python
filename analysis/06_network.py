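"""Build the patient-flow network; structural metrics and cluster flows."""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd

from hospiflow.pipeline import stage_network

if __name__ == "__main__":
    d = stage_network(common.CONFIG)
    metrics = json.loads((d / "network_metrics.json").read_text())
    for mode in ("all", "strong"):
        m = metrics[mode]
        print(f"{mode:>6}: assortativity {m['assortativity_degree']:+.3f}  "
              f"transitivity {m['transitivity_global']:.3f}  "
              f"density {m['edge_density']:.3f}  edges {m['n_edges']}")
    flows = pd.read_csv(d / "flow_counts.csv", index_col="from_cluster")
    print("\ninter-cluster event counts:")
    print(flows.to_string())
    print("\nA negative assortativity marks a hub-and-spoke referral system: "
          "small hospitals send patients to a few large centers.")
    common.publish("network_metrics.json", "flow_counts.csv")
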