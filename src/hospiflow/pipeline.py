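"""Pipeline orchestration: configuration, staged runs, persisted artifacts.

A run directory accumulates the outputs of the stages in order::

    simulate -> stays.csv registry.csv truth.csv
    ingest   -> filtered_stays.csv exclusion_ledger.csv rejects.csv
    mobility -> events.csv mobility_diagnostics.json
    features -> features.csv standardization.json
    cluster  -> kselect.json assignments.csv model.json
                cluster_profiles.csv domain_counts.csv domain_pct.csv
    network  -> network_all.graphml network_strong.graphml
                network_metrics.json flow_counts.csv
    report   -> report/

Every stage is a pure function of (inputs, config, seed); each run writes
its resolved configuration next to its outputs.  ``analyze`` performs the
whole analysis in memory for library use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import ingest as ingest_mod
from . import report as report_mod
from . import synth as synth_mod
from .cluster import ClusterModel, kmeans, profile_clusters, select_k
from .features import ACTIVE_VARIABLES, compute_features, standardize
from .mobility import detect_mobility
from .network import build_network, compute_metrics, flow_matrix


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    run_dir: str = "run"
    stays_csv: str | None = None  # if None, the simulate stage must provide them
    registry_csv: str | None = None
    # synthetic generator knobs (used by the simulate stage)
    synth_volume_scale: float = 1.0
    synth_hospitals: tuple[int, int, int] = (34, 236, 157)
    synth_overrides: dict = field(default_factory=dict)
    # thresholds
    min_annual_stays: int = 500
    receiving_los_min_hours: float = 48.0
    window_days: int = 90
    strong_threshold: int = 100
    # clustering
    k: int | None = None  # fixed k; None = majority rule over k_range
    k_range: tuple[int, ...] = tuple(range(2, 9))
    n_restarts: int = 50
    init: str = "k-means++"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_annual_stays", "window_days", "strong_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.receiving_los_min_hours < 0:
            raise ConfigError("receiving_los_min_hours must be non-negative")
        if not self.k_range:
            raise ConfigError("k_range must be nonempty")
        if self.k is not None and self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.synth_volume_scale <= 0:
            raise ConfigError("synth_volume_scale must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(int(k) for k in raw["k_range"])
        if "synth_hospitals" in raw:
            raw["synth_hospitals"] = tuple(int(n) for n in raw["synth_hospitals"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["synth_hospitals"] = list(self.synth_hospitals)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class AnalysisResult:
    """In-memory result of the full analysis."""

    filtered_stays: pd.DataFrame
    exclusion_ledger: pd.DataFrame
    events: pd.DataFrame
    diagnostics: dict
    features: pd.DataFrame
    standardized: "object"
    kselection: "object | None"
    model: ClusterModel
    profiles: dict
    network_all: nx.DiGraph
    network_strong: nx.DiGraph
    metrics_all: "object"
    metrics_strong: "object"
    flow: "object"


def analyze(
    stays: pd.DataFrame,
    registry: pd.DataFrame,
    *,
    min_annual_stays: int = 500,
    receiving_los_min_hours: float = 48.0,
    window_days: int = 90,
    strong_threshold: int = 100,
    k: int | None = None,
    k_range=tuple(range(2, 9)),
    seed: int = 0,
    n_restarts: int = 50,
    init: str = "k-means++",
) -> AnalysisResult:
    """Run the full analysis in memory on validated stay/registry tables."""
    filtered, ledger = ingest_mod.apply_exclusions(
        stays, registry, min_annual_stays=min_annual_stays,
        receiving_los_min_hours=receiving_los_min_hours,
    )
    if filtered.empty:
        raise ValueError("no stays survive the exclusion filters")
    events, diagnostics = detect_mobility(filtered, registry, window_days=window_days)
    feats = compute_features(filtered, events, registry)
    std = standardize(feats)

    kreport = None
    if k is None:
        kreport = select_k(std.values, k_range=k_range, seed=seed, n_restarts=n_restarts, init=init)
        model = kreport.models[kreport.majority_k]
    else:
        model = kmeans(std.values, k, seed=seed, n_restarts=n_restarts, init=init)

    profiles = profile_clusters(model, feats, registry, filtered)
    labels = model.assignments
    net_all = build_network(events, labels, registry, strong_threshold, mode="all")
    net_strong = build_network(events, labels, registry, strong_threshold, mode="strong")
    metrics_all = compute_metrics(net_all)
    metrics_strong = compute_metrics(net_strong)
    flow = flow_matrix(events, labels) if len(events) else None

    return AnalysisResult(
        filtered_stays=filtered,
        exclusion_ledger=ledger,
        events=events,
        diagnostics=diagnostics,
        features=feats,
        standardized=std,
        kselection=kreport,
        model=model,
        profiles=profiles,
        network_all=net_all,
        network_strong=net_strong,
        metrics_all=metrics_all,
        metrics_strong=metrics_strong,
        flow=flow,
    )


# ---------------------------------------------------------------------------
# staged, persisted pipeline


def _run_dir(config: PipelineConfig) -> Path:
    d = Path(config.run_dir)
    d.mkdir(parents=True, exist_ok=True)
    config.to_yaml(d / "resolved_config.yaml")
    return d


def stage_simulate(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    synth_cfg = synth_mod.reference_config(
        volume_scale=config.synth_volume_scale,
        hospitals=config.synth_hospitals,
        seed=config.seed,
        **config.synth_overrides,
    )
    stays, registry, truth = synth_mod.generate_stays(synth_cfg)
    stays.to_csv(d / "stays.csv", index=False, date_format="%Y-%m-%d")
    registry.to_csv(d / "registry.csv", index=False)
    truth.to_csv(d / "truth.csv", index=False)
    return d


def _load_inputs(config: PipelineConfig, d: Path):
    stays_path = config.stays_csv or d / "stays.csv"
    registry_path = config.registry_csv or d / "registry.csv"
    for p, stage in ((stays_path, "simulate"), (registry_path, "simulate")):
        if not Path(p).exists():
            raise FileNotFoundError(f"input {p} not found (run the '{stage}' stage or point the config at data)")
    return ingest_mod.load_stays(stays_path, registry_path)


def stage_ingest(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    loaded = _load_inputs(config, d)
    filtered, ledger = ingest_mod.apply_exclusions(
        loaded.stays,
        loaded.registry,
        min_annual_stays=config.min_annual_stays,
        receiving_los_min_hours=config.receiving_los_min_hours,
    )
    filtered.to_csv(d / "filtered_stays.csv", index=False, date_format="%Y-%m-%d")
    ledger.to_csv(d / "exclusion_ledger.csv", index=False)
    loaded.rejects.to_csv(d / "rejects.csv", index=False)
    return d


def _read_filtered(d: Path) -> pd.DataFrame:
    p = d / "filtered_stays.csv"
    if not p.exists():
        raise FileNotFoundError("filtered_stays.csv not found (run the 'ingest' stage)")
    return pd.read_csv(p, parse_dates=["entry_date", "discharge_date"])


def _read_registry(config: PipelineConfig, d: Path) -> pd.DataFrame:
    path = config.registry_csv or d / "registry.csv"
    return ingest_mod.load_registry(path)


def stage_mobility(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    filtered = _read_filtered(d)
    registry = _read_registry(config, d)
    events, diagnostics = detect_mobility(filtered, registry, window_days=config.window_days)
    events.to_csv(d / "events.csv", index=False, date_format="%Y-%m-%d")
    (d / "mobility_diagnostics.json").write_text(json.dumps(diagnostics, indent=2, sort_keys=True) + "\n")
    return d


def _read_events(d: Path) -> pd.DataFrame:
    p = d / "events.csv"
    if not p.exists():
        raise FileNotFoundError("events.csv not found (run the 'mobility' stage)")
    return pd.read_csv(p, parse_dates=["index_discharge_date", "next_entry_date"])


def stage_features(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    filtered = _read_filtered(d)
    registry = _read_registry(config, d)
    events = _read_events(d)
    feats = compute_features(filtered, events, registry)
    std = standardize(feats)
    feats.to_csv(d / "features.csv")
    (d / "standardization.json").write_text(
        json.dumps(
            {"mean": std.mean.to_dict(), "std": std.std.to_dict(), "ddof": std.ddof},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return d


def stage_cluster(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    feats = pd.read_csv(d / "features.csv", index_col="hospital_id")
    std = standardize(feats)
    registry = _read_registry(config, d)
    filtered = _read_filtered(d)

    if config.k is None:
        kreport = select_k(
            std.values, k_range=config.k_range, seed=config.seed,
            n_restarts=config.n_restarts, init=config.init,
        )
        model = kreport.models[kreport.majority_k]
        votes = kreport.votes
        wss_curve = kreport.wss_curve
        candidate_ks = list(kreport.candidate_ks)
        majority_k = kreport.majority_k
    else:
        model = kmeans(std.values, config.k, seed=config.seed,
                       n_restarts=config.n_restarts, init=config.init)
        votes = {}
        wss_curve = {config.k: model.wss}
        candidate_ks = [config.k]
        majority_k = config.k

    (d / "kselect.json").write_text(
        json.dumps(
            {
                "candidate_ks": candidate_ks,
                "votes": votes,
                "majority_k": majority_k,
                "wss_curve": {str(k): w for k, w in sorted(wss_curve.items())},
                "seed": config.seed,
                "n_restarts": config.n_restarts,
                "init": config.init,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    model.assignments.rename("cluster").to_csv(d / "assignments.csv", index_label="hospital_id")
    (d / "model.json").write_text(
        json.dumps(
            {
                "k": model.k,
                "centroids": [[round(v, 10) for v in row] for row in model.centroids.tolist()],
                "wss": model.wss,
                "n_iterations": model.n_iterations,
                "seed": model.seed,
                "n_restarts": model.n_restarts,
                "init": model.init,
                "variables": list(ACTIVE_VARIABLES),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    prof = profile_clusters(model, feats, registry, filtered)
    prof["profiles"].to_csv(d / "cluster_profiles.csv")
    prof["domain_counts"].to_csv(d / "domain_counts.csv")
    prof["domain_pct"].round(4).to_csv(d / "domain_pct.csv")
    return d


def stage_network(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    events = _read_events(d)
    registry = _read_registry(config, d)
    labels = pd.read_csv(d / "assignments.csv", index_col="hospital_id")["cluster"]

    nets = {}
    metrics = {}
    for mode in ("all", "strong"):
        g = build_network(events, labels, registry, config.strong_threshold, mode=mode)
        nets[mode] = g
        m = compute_metrics(g).to_dict()
        m["threshold"] = config.strong_threshold if mode == "strong" else 0
        metrics[mode] = m
        nx.write_graphml(g, d / f"network_{mode}.graphml")
    (d / "network_metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")

    if len(events):
        fm = flow_matrix(events, labels)
        fm.counts.to_csv(d / "flow_counts.csv")
    else:
        pd.DataFrame().to_csv(d / "flow_counts.csv")
    return d


def stage_report(config: PipelineConfig) -> Path:
    config.validate()
    d = _run_dir(config)
    report_mod.render(d)
    return d


def reference_pipeline_config(
    run_dir: str = "scratch/reference_run",
    seed: int = 0,
    volume_scale: float = 0.5,
    hospitals: tuple[int, int, int] = (34, 236, 157),
) -> PipelineConfig:
    """Study-conditions configuration at a reduced problem size.

    ``volume_scale`` scales the per-archetype volume medians jointly and the
    two absolute-count thresholds with them (minimum annual stays, strong-edge
    patient count), preserving the study geometry at a fraction of the data
    volume.
    """
    return PipelineConfig(
        run_dir=run_dir,
        synth_volume_scale=volume_scale,
        synth_hospitals=hospitals,
        min_annual_stays=max(1, round(500 * volume_scale)),
        strong_threshold=max(1, round(100 * volume_scale)),
        n_restarts=20,
        seed=seed,
    )


STAGES = {
    "simulate": stage_simulate,
    "ingest": stage_ingest,
    "mobility": stage_mobility,
    "features": stage_features,
    "cluster": stage_cluster,
    "network": stage_network,
    "report": stage_report,
}

STAGE_ORDER = ("simulate", "ingest", "mobility", "features", "cluster", "network", "report")


def run_all(config: PipelineConfig) -> Path:
    """Chain every stage; skips 'simulate' when the config points at data."""
    stages = list(STAGE_ORDER)
    if config.stays_csv is not None:
        stages.remove("simulate")
    d = None
    for name in stages:
        d = STAGES[name](config)
    return d
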