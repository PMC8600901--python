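"""Report assembly and sensitivity analysis.

``render`` turns the persisted intermediates of a pipeline run into the
report tables: cluster profiles, the per-cluster activity-domain breakdown,
the inter-cluster flow table, plot-ready data for the absolute-vs-effective
domain comparison, the elbow curve and the cluster scatter, plus a JSON
summary.  Every number in the report is recomputable from the run's
intermediates; rendering the same run directory twice is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import kmeans
from .features import ACTIVE_VARIABLES
from .mobility import window_profile, within_rhg_share


class MissingIntermediateError(FileNotFoundError):
    """A report input produced by an earlier pipeline stage is absent."""


def label_agreement(a: pd.Series, b: pd.Series) -> float:
    """Fraction of points whose cluster is stable under optimal label matching.

    K-means labels are arbitrary, so raw label comparison overstates change;
    the confusion matrix is matched by the Hungarian algorithm and agreement
    is the matched mass over n.
    """
    a, b = a.align(b, join="inner")
    if len(a) == 0:
        raise ValueError("no common points to compare")
    conf = pd.crosstab(a, b).to_numpy()
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(a))


def sensitivity_omit_variable(
    standardized: pd.DataFrame,
    variable: str,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> float:
    """Percent of hospitals changing cluster when one variable is omitted.

    Refits k-means at the same k without the named column and reports the
    minimum disagreement over cluster-label permutations, in percent.
    """
    if variable not in standardized.columns:
        raise ValueError(f"unknown variable {variable!r}")
    remaining = [c for c in standardized.columns if c != variable]
    if not remaining:
        raise ValueError("omitting the variable would leave no features")
    base = kmeans(standardized, k, seed=seed, n_restarts=n_restarts)
    reduced = kmeans(standardized[remaining], k, seed=seed, n_restarts=n_restarts)
    return 100.0 * (1.0 - label_agreement(base.assignments, reduced.assignments))


def _need(run_dir: Path, name: str, stage: str) -> Path:
    p = run_dir / name
    if not p.exists():
        raise MissingIntermediateError(
            f"missing intermediate '{name}' (produced by stage '{stage}')"
        )
    return p


def _round_df(df: pd.DataFrame, ndigits: int = 4) -> pd.DataFrame:
    return df.round(ndigits)


def render(run_dir) -> dict[str, Path]:
    """Assemble the report from a completed run directory.

    Returns a mapping of section name to written path.  Raises
    :class:`MissingIntermediateError` naming the stage whose output is
    missing.
    """
    run_dir = Path(run_dir)
    out_dir = run_dir / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ledger = pd.read_csv(_need(run_dir, "exclusion_ledger.csv", "ingest"))
    features = pd.read_csv(_need(run_dir, "features.csv", "features"), index_col="hospital_id")
    events = pd.read_csv(
        _need(run_dir, "events.csv", "mobility"), parse_dates=["index_discharge_date", "next_entry_date"]
    )
    diagnostics = json.loads(_need(run_dir, "mobility_diagnostics.json", "mobility").read_text())
    kselect = json.loads(_need(run_dir, "kselect.json", "cluster").read_text())
    assignments = pd.read_csv(
        _need(run_dir, "assignments.csv", "cluster"), index_col="hospital_id"
    )["cluster"]
    profiles = pd.read_csv(_need(run_dir, "cluster_profiles.csv", "cluster"), index_col="cluster")
    domain_counts = pd.read_csv(
        _need(run_dir, "domain_counts.csv", "cluster"), index_col="activity_domain"
    )
    metrics = json.loads(_need(run_dir, "network_metrics.json", "network").read_text())
    flow_counts = pd.read_csv(_need(run_dir, "flow_counts.csv", "network"), index_col="from_cluster")
    std_meta = json.loads(_need(run_dir, "standardization.json", "features").read_text())

    # Table 1 analogue
    p = _round_df(profiles)
    p.to_csv(out_dir / "table1_profiles.csv")
    written["table1_profiles"] = out_dir / "table1_profiles.csv"

    # Table 2 analogue: counts + percentages, columns sum to 100
    totals = domain_counts.sum(axis=0)
    pct = (100.0 * domain_counts / totals).round(1)
    tab2 = pd.concat({"count": domain_counts, "pct": pct}, axis=1)
    tab2.to_csv(out_dir / "table2_activity_domains.csv")
    written["table2_activity_domains"] = out_dir / "table2_activity_domains.csv"

    # Table 3 analogue: long format with printed-style whole-percent rounding
    total = flow_counts.to_numpy().sum()
    rows = []
    for frm in flow_counts.index:
        row_total = flow_counts.loc[frm].sum()
        for to in flow_counts.columns:
            c = int(flow_counts.loc[frm, to])
            rows.append(
                {
                    "from_cluster": frm,
                    "to_cluster": to,
                    "count": c,
                    "row_pct": int(round(100.0 * c / row_total)) if row_total else 0,
                    "overall_pct": int(round(100.0 * c / total)) if total else 0,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "table3_flows.csv", index=False)
    written["table3_flows"] = out_dir / "table3_flows.csv"

    # Figure data
    fig2 = features[["n_domains_absolute", "n_domains_effective"]].sort_index()
    fig2.to_csv(out_dir / "fig2_absolute_vs_effective.csv")
    written["fig2_absolute_vs_effective"] = out_dir / "fig2_absolute_vs_effective.csv"

    elbow = pd.DataFrame(
        sorted((int(k), w) for k, w in kselect["wss_curve"].items()),
        columns=["k", "wss"],
    )
    elbow.to_csv(out_dir / "fig3_elbow.csv", index=False)
    written["fig3_elbow"] = out_dir / "fig3_elbow.csv"

    fig4 = features.join(assignments, how="inner").sort_index()
    _round_df(fig4).to_csv(out_dir / "fig4_scatter.csv")
    written["fig4_scatter"] = out_dir / "fig4_scatter.csv"

    # sensitivity: refit without the effective-diversity variable
    std = (features[list(ACTIVE_VARIABLES)] - pd.Series(std_meta["mean"])) / pd.Series(
        std_meta["std"]
    )
    sens = sensitivity_omit_variable(
        std,
        "n_domains_effective",
        k=int(kselect["majority_k"]),
        seed=int(kselect["seed"]),
        n_restarts=int(kselect["n_restarts"]),
    )

    if len(events):
        win = window_profile(events)
        share_all = within_rhg_share(events)
        try:
            share_strong = within_rhg_share(events, min_pair_weight=metrics["strong"]["threshold"])
        except ValueError:
            share_strong = None
        window = {str(k): round(float(v), 6) for k, v in win.items()}
    else:
        window, share_all, share_strong = {}, None, None

    summary = {
        "schema_version": 1,
        "exclusion_ledger": {r.rule: int(r.n_removed) for r in ledger.itertuples()},
        "n_hospitals": int(len(features)),
        "n_stays": int(features["n_stays"].sum()),
        "n_events": int(len(events)),
        "mobility_diagnostics": diagnostics,
        "k_selection": {
            "votes": kselect["votes"],
            "majority_k": kselect["majority_k"],
            "candidate_ks": kselect["candidate_ks"],
        },
        "cluster_sizes": {str(c): int(n) for c, n in assignments.value_counts().sort_index().items()},
        "network": metrics,
        "flow_grand_total": int(total),
        "within_rhg_share": None if share_all is None else round(float(share_all), 6),
        "within_rhg_share_strong_pairs": None if share_strong is None else round(float(share_strong), 6),
        "window_profile": window,
        "sensitivity_omit_effective_domains_pct": round(float(sens), 4),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written["summary"] = out_dir / "summary.json"
    return written
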