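"""Assemble the final report tables."""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from hospiflow.pipeline import stage_report

if __name__ == "__main__":
    d = stage_report(common.CONFIG)
    summary = json.loads((d / "report" / "summary.json").read_text())
    print(f"hospitals: {summary['n_hospitals']}  stays: {summary['n_stays']:,}  "
          f"events: {summary['n_events']:,}")
    print(f"cluster sizes: {summary['cluster_sizes']}")
    print(f"omitting the effective-diversity variable moves "
          f"{summary['sensitivity_omit_effective_domains_pct']:.1f}% of hospitals")
    common.publish(
        "report/summary.json", "report/table1_profiles.csv",
        "report/table2_activity_domains.csv", "report/table3_flows.csv",
        "report/fig3_elbow.csv",
    )
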