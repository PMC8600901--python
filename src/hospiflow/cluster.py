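"""K-means hospital profiling with data-driven choice of k.

The number of clusters is chosen by a majority rule over several internal
validity indices (silhouette and Calinski-Harabasz maximize, Davies-Bouldin
minimizes, Hartigan takes the first k where its statistic drops below 10),
then verified against the elbow of the within-cluster sum-of-squares curve.
K-means itself is Lloyd's algorithm, best of ``n_restarts`` initializations
by WSS; k-means++ seeding is the default, plain random seeding is available
to mirror the classical description of the algorithm.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

DEFAULT_K_RANGE = tuple(range(2, 9))
HARTIGAN_THRESHOLD = 10.0


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, n_vars) in standardized space
    assignments: pd.Series  # hospital_id -> cluster label (0..k-1)
    wss: float
    n_iterations: int
    seed: int
    n_restarts: int
    init: str = "k-means++"
    variables: tuple[str, ...] = ()

    def recompute_wss(self, X: pd.DataFrame) -> float:
        """WSS from scratch — squared distance of each point to its centroid."""
        x = np.asarray(X, dtype=float)
        lab = self.assignments.reindex(X.index).to_numpy()
        return float(np.sum((x - self.centroids[lab]) ** 2))


def _as_matrix(features) -> tuple[np.ndarray, pd.Index, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), features.index, tuple(features.columns)
    x = np.asarray(features, dtype=float)
    return x, pd.RangeIndex(len(x)), ()


def kmeans(
    features,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 300,
    init: str = "k-means++",
) -> ClusterModel:
    """Fit k-means on a (hospitals x variables) matrix of standardized features.

    Best of ``n_restarts`` runs by within-cluster sum of squares.  Duplicate
    points are allowed; ``k`` larger than the number of points is an error.
    """
    x, index, variables = _as_matrix(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the number of points ({len(x)})")
    km = KMeans(
        n_clusters=k,
        init=init,
        n_init=n_restarts,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    ).fit(x)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=pd.Series(km.labels_, index=index, name="cluster"),
        wss=float(km.inertia_),
        n_iterations=int(km.n_iter_),
        seed=seed,
        n_restarts=n_restarts,
        init=init,
        variables=variables,
    )


@dataclass
class KSelectionReport:
    candidate_ks: tuple[int, ...]
    votes: dict[str, int]  # index name -> chosen k
    majority_k: int
    wss_curve: dict[int, float]  # k -> wss (elbow data), includes k = 1
    models: dict[int, ClusterModel] = field(default_factory=dict, repr=False)


def hartigan_statistic(wss_k: float, wss_k1: float, n: int, k: int) -> float:
    """Hartigan's rule statistic H(k) = (W_k / W_{k+1} - 1) * (n - k - 1)."""
    if wss_k1 <= 0:
        return 0.0
    return (wss_k / wss_k1 - 1.0) * (n - k - 1)


def select_k(
    features,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    n_restarts: int = 50,
    init: str = "k-means++",
) -> KSelectionReport:
    """Majority-rule choice of the number of clusters.

    Fits k-means over ``k_range`` (plus k = 1 and k = max+1 for the elbow
    curve and Hartigan's statistic), lets each validity index vote, and
    returns the modal k, ties broken toward smaller k (parsimony).
    """
    x, index, _ = _as_matrix(features)
    n = len(x)
    if n < 3:
        raise ValueError("select_k needs at least 3 points")
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    fit_ks = sorted(set([1] + ks + [ks[-1] + 1]))
    models: dict[int, ClusterModel] = {}
    wss_curve: dict[int, float] = {}
    for k in fit_ks:
        if k > n:
            continue
        m = kmeans(features, k, seed=seed, n_restarts=n_restarts, init=init)
        models[k] = m
        wss_curve[k] = m.wss

    labels = {k: models[k].assignments.to_numpy() for k in ks}
    votes: dict[str, int] = {}
    sil = {k: silhouette_score(x, labels[k]) for k in ks}
    votes["silhouette"] = max(ks, key=lambda k: (sil[k], -k))
    ch = {k: calinski_harabasz_score(x, labels[k]) for k in ks}
    votes["calinski_harabasz"] = max(ks, key=lambda k: (ch[k], -k))
    db = {k: davies_bouldin_score(x, labels[k]) for k in ks}
    votes["davies_bouldin"] = min(ks, key=lambda k: (db[k], k))

    hart = {
        k: hartigan_statistic(wss_curve[k], wss_curve.get(k + 1, 0.0), n, k)
        for k in ks
        if k + 1 in wss_curve
    }
    below = [k for k, h in sorted(hart.items()) if h <= HARTIGAN_THRESHOLD]
    if below:
        votes["hartigan"] = below[0]
    else:
        # On low-dimensional continuous data, splitting any cluster keeps
        # cutting WSS by well over the threshold's implied fraction, so no k
        # qualifies; fall back to the largest drop of the statistic (its
        # elbow), the decision rule of the classical index batteries.
        drops = {k: hart[k - 1] - hart[k] for k in sorted(hart) if k - 1 in hart}
        votes["hartigan"] = max(drops, key=lambda k: (drops[k], -k)) if drops else min(hart)

    counts = Counter(votes.values())
    top = max(counts.values())
    majority_k = min(k for k, c in counts.items() if c == top)
    return KSelectionReport(
        candidate_ks=tuple(ks),
        votes=votes,
        majority_k=majority_k,
        wss_curve=wss_curve,
        models=models,
    )


def _mean_sd(s: pd.Series) -> tuple[float, float]:
    return float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else 0.0


def profile_clusters(
    model: ClusterModel,
    features: pd.DataFrame,
    registry: pd.DataFrame,
    stays: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-cluster summary profiles and the activity-domain breakdown.

    Returns ``{"profiles": ..., "domain_counts": ..., "domain_pct": ...}``.
    ``profiles`` has one row per cluster with hospital counts, volume and
    bed quartiles (linear-interpolation convention), mean (SD) of the
    mobility index and domain counts, and leader counts.  The domain tables
    give per-cluster stay counts by activity domain and their percentages,
    denominator = all stays of the cluster.
    """
    feats = features.join(model.assignments, how="inner")
    reg = registry.set_index("hospital_id")
    feats = feats.join(reg[["bed_count", "rhg_leader"]], how="left")

    rows = []
    for c, grp in feats.groupby("cluster"):
        q = grp["n_stays"].quantile([0.25, 0.5, 0.75])
        bq = grp["bed_count"].quantile([0.25, 0.5, 0.75])
        mob_m, mob_sd = _mean_sd(grp["mobility_index_pct"])
        abs_m, abs_sd = _mean_sd(grp["n_domains_absolute"].astype(float))
        eff_m, eff_sd = _mean_sd(grp["n_domains_effective"])
        rows.append(
            {
                "cluster": c,
                "n_hospitals": len(grp),
                "stays_median": q.loc[0.5],
                "stays_q1": q.loc[0.25],
                "stays_q3": q.loc[0.75],
                "beds_median": bq.loc[0.5],
                "beds_q1": bq.loc[0.25],
                "beds_q3": bq.loc[0.75],
                "mobility_mean": mob_m,
                "mobility_sd": mob_sd,
                "domains_absolute_mean": abs_m,
                "domains_absolute_sd": abs_sd,
                "domains_effective_mean": eff_m,
                "domains_effective_sd": eff_sd,
                "n_leaders": int(grp["rhg_leader"].fillna(False).sum()),
            }
        )
    profiles = pd.DataFrame(rows).set_index("cluster").sort_index()

    lab = model.assignments
    st = stays.loc[stays["hospital_id"].isin(lab.index)].copy()
    st["cluster"] = st["hospital_id"].map(lab)
    counts = (
        st.groupby(["activity_domain", "cluster"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    pct = domain_percentages(counts)
    return {"profiles": profiles, "domain_counts": counts, "domain_pct": pct}


def domain_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage of cluster activity per domain.

    ``counts`` is (domains x clusters); each column is divided by the
    cluster's total stays and expressed in percent, so columns sum to 100.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("domain_percentages: a cluster has zero stays")
    return 100.0 * counts / totals
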