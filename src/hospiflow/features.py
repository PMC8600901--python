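"""Per-hospital clustering variables.

Three "active" variables characterize each hospital:

* ``n_stays`` — annual volume, a proxy for hospital size;
* ``n_domains_effective`` — the effective number of activity domains, the
  inverse-Simpson diversity (Hill number of order 2) of the hospital's
  distribution of stays over activity domains,

  .. math:: D = 1 / \\sum_i p_i^2

  where :math:`p_i` is the proportion of the hospital's stays in domain
  :math:`i`.  Unlike the raw count of domains with at least one stay, D is
  dominated by the domains a hospital practices *regularly*: a hospital with
  500 stays in one domain and a handful elsewhere has D barely above 1.
* ``mobility_index_pct`` — the percentage of stays followed, within 90 days,
  by a stay in another hospital of the same regional hospital group.

Before clustering, variables are z-scored (unweighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mobility import mobility_index

#: Column names of the active variables, in clustering order.
ACTIVE_VARIABLES = ("n_stays", "n_domains_effective", "mobility_index_pct")

FEATURE_COLUMNS = (
    "n_stays",
    "n_domains_absolute",
    "n_domains_effective",
    "mobility_index_pct",
)


def effective_domains(domain_counts) -> float:
    """Inverse-Simpson effective number of activity domains.

    Parameters
    ----------
    domain_counts : array-like or mapping
        Stay counts per activity domain; zero entries are ignored.

    Returns
    -------
    float
        ``1 / sum(p_i**2)`` with ``p_i`` the per-domain proportions.
        Equals the number of represented domains iff their counts are equal,
        and is scale-invariant in the counts.
    """
    if isinstance(domain_counts, dict):
        counts = np.asarray(list(domain_counts.values()), dtype=float)
    else:
        counts = np.asarray(domain_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("effective_domains: empty count vector")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("effective_domains: counts must be finite and non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("effective_domains: all counts are zero")
    p = counts / total
    return float(1.0 / np.square(p).sum())


def compute_features(
    stays: pd.DataFrame, events: pd.DataFrame, registry: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the per-hospital feature table.

    One row per hospital present in ``stays``: volume, absolute and effective
    domain counts, and the same-group mobility index (percent).  Hospitals
    appearing in the stay table but missing from the registry are an error:
    the registry is the authority on which hospitals exist.
    """
    missing = set(stays["hospital_id"].unique()) - set(registry["hospital_id"])
    if missing:
        raise ValueError(
            f"hospitals present in stays but absent from registry: {sorted(missing)[:5]}"
        )

    grouped = stays.groupby("hospital_id", sort=True, observed=True)
    n_stays = grouped.size()
    domain_tab = (
        stays.groupby(["hospital_id", "activity_domain"], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    n_abs = (domain_tab > 0).sum(axis=1)
    p = domain_tab.div(domain_tab.sum(axis=1), axis=0)
    n_eff = 1.0 / np.square(p).sum(axis=1)

    mob = mobility_index(events, stays, registry)

    out = pd.DataFrame(
        {
            "n_stays": n_stays.astype(int),
            "n_domains_absolute": n_abs.astype(int),
            "n_domains_effective": n_eff.astype(float),
            "mobility_index_pct": mob.reindex(n_stays.index).fillna(0.0),
        }
    )
    out.index.name = "hospital_id"
    return out.sort_index()


@dataclass
class StandardizedFeatures:
    """Z-scored feature matrix with the location/scale used to produce it."""

    values: pd.DataFrame
    mean: pd.Series
    std: pd.Series
    ddof: int = 1

    def inverse(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Map z-scores back to the original scale."""
        v = self.values if values is None else values
        return v * self.std + self.mean


def standardize(
    features: pd.DataFrame,
    variables: tuple[str, ...] = ACTIVE_VARIABLES,
    ddof: int = 1,
) -> StandardizedFeatures:
    """Column-wise z-scoring of the active variables.

    Uses the sample standard deviation (``ddof=1``) by default; the choice is
    recorded on the result so a run is reproducible under either convention.
    A constant column cannot be standardized and raises, naming the variable.
    """
    if len(features) < 2:
        raise ValueError("standardize requires at least 2 hospitals")
    x = features[list(variables)].astype(float)
    mean = x.mean()
    std = x.std(ddof=ddof)
    dead = std[~(std > 0)].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    z = (x - mean) / std
    return StandardizedFeatures(values=z, mean=mean, std=std, ddof=ddof)
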