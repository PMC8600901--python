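"""Synthetic discharge-record generator.

Emulates the structure of a one-year national hospital claims extraction:
hospitals drawn from a small number of latent archetypes (reference centers,
medium general hospitals, small local hospitals) that differ in annual
volume, activity-domain concentration, and propensity to send patients on to
other hospitals; a registry assigning hospitals to regional groups; and an
asymmetric (disassortative) inter-archetype referral flow.

The real database is access-restricted, so every downstream stage is tested
against this generator.  Distributional forms are stand-ins chosen for
plausibility (the study reports only summary statistics, no distributions):

* per-hospital volume: log-normal around the archetype median — heavy right
  tail matching the wide printed interquartile ranges;
* per-hospital effective diversity: a truncated-normal target around the
  archetype mean, realized by solving a geometric base profile over the
  activity domains for the exact inverse-Simpson value, then perturbing it
  with a tight Dirichlet draw;
* mobility: each index stay independently spawns at most one follow-up stay
  in another hospital, with a per-hospital rate jittered log-normally around
  the archetype target; a configurable share of follow-ups are same-day
  transfers, the rest uniform readmissions within the 90-day window.

Follow-up stays get lengths of stay of at least two days by default, so
they survive the short-transfer exclusion; a configurable fraction of
sub-48 h transfers can be injected to exercise that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import published

_EMPTY = np.array([], dtype=np.int64)

__all__ = ["ArchetypeSpec", "SynthConfig", "generate_stays", "reference_config", "base_profile"]


@dataclass
class ArchetypeSpec:
    """One latent hospital archetype."""

    name: str
    n_hospitals: int
    mean_annual_stays: float  # median of the log-normal volume distribution
    stay_dispersion: float  # log-scale sigma of per-hospital volumes
    effective_domains: float  # archetype mean of the inverse-Simpson diversity
    effective_domains_sd: float  # between-hospital SD of the diversity target
    target_mobility_rate: float  # P(index stay followed by a stay elsewhere <= 90 d)
    referral_mix: dict[str, float]  # archetype -> fraction of outgoing mobility
    profile_concentration: float = 3000.0  # Dirichlet tightness around the base profile
    mobility_dispersion: float = 0.25  # log-sd of per-hospital mobility rates

    def __post_init__(self) -> None:
        if self.n_hospitals <= 0 or self.mean_annual_stays <= 0:
            raise ValueError(f"archetype {self.name!r}: counts must be positive")
        if not 0.0 <= self.target_mobility_rate <= 1.0:
            raise ValueError(f"archetype {self.name!r}: target_mobility_rate outside [0, 1]")
        if self.stay_dispersion < 0 or self.effective_domains < 1:
            raise ValueError(f"archetype {self.name!r}: invalid dispersion/diversity")
        total = sum(self.referral_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype {self.name!r}: referral_mix sums to {total}, not 1")


@dataclass
class SynthConfig:
    archetypes: list[ArchetypeSpec]
    n_domains: int = 25
    n_regional_groups: int = 136
    year_start: date = date(2016, 1, 1)
    year_end: date = date(2016, 12, 31)
    rhg_flow_alignment: float = 0.455  # P(referral target sought in sender's group)
    transfer_fraction: float = 0.436  # share of follow-ups entering on the discharge day
    short_transfer_fraction: float = 0.0  # share of transfers given LOS < 48 h
    invalid_fraction: float = 0.0
    iterative_fraction: float = 0.0
    index_los_mean: float = 3.0  # days; Poisson
    followup_los_mean: float = 2.0  # days beyond the 2-day floor; Poisson
    window_days: int = 90
    seed: int = 0
    max_total_stays: int = 20_000_000

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        if self.year_start >= self.year_end:
            raise ValueError("year_start must precede year_end")
        names = {a.name for a in self.archetypes}
        for a in self.archetypes:
            unknown = set(a.referral_mix) - names
            if unknown:
                raise ValueError(f"archetype {a.name!r}: referral_mix targets unknown {unknown}")


def base_profile(target_diversity: float, n_domains: int) -> np.ndarray:
    """Geometric probability vector with a prescribed inverse-Simpson value.

    p_i proportional to r**i, with r solved so 1/sum(p_i^2) equals the
    target.  r = 1 gives the uniform profile (diversity = n_domains); r -> 0
    concentrates all mass on one domain (diversity -> 1).
    """
    if not 1.0 <= target_diversity <= n_domains:
        raise ValueError(
            f"target diversity {target_diversity} outside [1, {n_domains}]"
        )
    idx = np.arange(n_domains)

    def inv_simpson(r: float) -> float:
        p = r**idx
        p = p / p.sum()
        return float(1.0 / np.square(p).sum())

    if target_diversity >= n_domains - 1e-9:
        return np.ones(n_domains) / n_domains
    if target_diversity <= 1.0 + 1e-12:
        p = np.zeros(n_domains)
        p[0] = 1.0
        return p
    r = brentq(lambda r: inv_simpson(r) - target_diversity, 1e-9, 1 - 1e-12, xtol=1e-13)
    p = r**idx
    return p / p.sum()


def _expected_total_stays(config: SynthConfig) -> float:
    total = 0.0
    for a in config.archetypes:
        mean = a.mean_annual_stays * np.exp(a.stay_dispersion**2 / 2)
        total += a.n_hospitals * mean * (1 + a.target_mobility_rate)
    return total


def generate_stays(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (stay table, hospital registry, truth labels).

    Deterministic given the config (the seed lives on the config).  Raises
    if the expected stay volume exceeds ``config.max_total_stays``.
    """
    expected = _expected_total_stays(config)
    if expected > config.max_total_stays:
        raise ValueError(
            f"config would generate ~{expected:.0f} stays, above the cap "
            f"of {config.max_total_stays}; lower volumes or raise max_total_stays"
        )
    rng = np.random.default_rng(config.seed)
    n_days = (config.year_end - config.year_start).days + 1
    year0 = np.datetime64(config.year_start.isoformat(), "D")

    # --- hospitals -------------------------------------------------------
    arch_names: list[str] = []
    for a in config.archetypes:
        arch_names.extend([a.name] * a.n_hospitals)
    n_hosp = len(arch_names)
    hospital_ids = np.array([f"H{i:04d}" for i in range(n_hosp)])
    arch_of = np.array(arch_names)
    arch_index = {a.name: i for i, a in enumerate(config.archetypes)}

    # regional groups: interleave archetypes so most groups mix tiers
    rhg_of = np.array(
        [f"R{i % config.n_regional_groups:03d}" for i in range(n_hosp)]
    )

    volumes = np.empty(n_hosp, dtype=np.int64)
    mob_rate = np.empty(n_hosp)
    profiles = np.empty((n_hosp, config.n_domains))
    for h in range(n_hosp):
        a = config.archetypes[arch_index[arch_of[h]]]
        volumes[h] = max(1, round(a.mean_annual_stays * np.exp(a.stay_dispersion * rng.standard_normal())))
        mob_rate[h] = min(1.0, a.target_mobility_rate * np.exp(a.mobility_dispersion * rng.standard_normal()))
        target = float(
            np.clip(
                rng.normal(a.effective_domains, a.effective_domains_sd),
                1.3,
                config.n_domains - 0.5,
            )
        )
        base = base_profile(target, config.n_domains)
        # tight Dirichlet perturbation; guard zero alphas
        alpha = np.maximum(a.profile_concentration * base, 1e-3)
        profiles[h] = rng.dirichlet(alpha)

    beds = np.maximum(5, np.round(volumes / 73.0 * np.exp(0.15 * rng.standard_normal(n_hosp)))).astype(int)
    leader = np.zeros(n_hosp, dtype=bool)
    for g in np.unique(rhg_of):
        members = np.flatnonzero(rhg_of == g)
        leader[members[np.argmax(volumes[members])]] = True

    registry = pd.DataFrame(
        {
            "hospital_id": hospital_ids,
            "rhg_id": rhg_of,
            "excluded_reason": "",
            "bed_count": beds,
            "rhg_leader": leader,
        }
    )
    truth = pd.DataFrame({"hospital_id": hospital_ids, "archetype": arch_of})

    # --- index stays -----------------------------------------------------
    total = int(volumes.sum())
    hosp_idx = np.repeat(np.arange(n_hosp), volumes)
    entry_off = rng.integers(0, n_days, size=total)
    los = rng.poisson(config.index_los_mean, size=total)
    domains = np.empty(total, dtype=np.int64)
    pos = 0
    for h in range(n_hosp):
        nh = volumes[h]
        domains[pos : pos + nh] = rng.choice(config.n_domains, size=nh, p=profiles[h])
        pos += nh
    patient_ids = np.char.add("P", np.arange(total).astype(str))

    # --- follow-up stays -------------------------------------------------
    spawn = rng.random(total) < mob_rate[hosp_idx]
    spawn_idx = np.flatnonzero(spawn)
    n_follow = spawn_idx.size

    # lookup tables: hospitals by archetype, by regional group, and crosses
    by_arch = {a.name: np.flatnonzero(arch_of == a.name) for a in config.archetypes}
    by_rhg = {g: np.flatnonzero(rhg_of == g) for g in np.unique(rhg_of)}
    by_rhg_arch: dict[tuple[str, str], np.ndarray] = {}
    out_of_rhg_arch: dict[tuple[str, str], np.ndarray] = {}
    for g in by_rhg:
        for a in config.archetypes:
            members = np.flatnonzero((rhg_of == g) & (arch_of == a.name))
            if members.size:
                by_rhg_arch[(g, a.name)] = members
            out_of_rhg_arch[(g, a.name)] = np.flatnonzero(
                (rhg_of != g) & (arch_of == a.name)
            )

    mix_names = [a.name for a in config.archetypes]
    mix_probs = {}
    for a in config.archetypes:
        probs = np.array([a.referral_mix.get(n, 0.0) for n in mix_names])
        mix_probs[a.name] = probs / probs.sum()

    target_arch = np.empty(n_follow, dtype=object)
    for name, probs in mix_probs.items():
        mask = arch_of[hosp_idx[spawn_idx]] == name
        target_arch[mask] = rng.choice(mix_names, size=int(mask.sum()), p=probs)
    in_group = rng.random(n_follow) < config.rhg_flow_alignment
    pick = rng.random(n_follow)

    # The same-group / out-of-group decision comes first so the realized
    # same-group share tracks rhg_flow_alignment; within that choice the
    # referral-mix archetype is preferred, then any available hospital.
    to_hosp = np.empty(n_follow, dtype=np.int64)
    for i in range(n_follow):
        sender = hosp_idx[spawn_idx[i]]
        g = rhg_of[sender]
        if in_group[i]:
            cands = by_rhg_arch.get((g, target_arch[i]), _EMPTY)
            cands = cands[cands != sender]
            if cands.size == 0:
                cands = by_rhg[g]
                cands = cands[cands != sender]
        else:
            cands = out_of_rhg_arch[(g, target_arch[i])]
        if cands.size == 0:  # degenerate geometry: go anywhere else
            cands = np.flatnonzero(np.arange(n_hosp) != sender)
        to_hosp[i] = cands[int(pick[i] * cands.size)]

    is_transfer = rng.random(n_follow) < config.transfer_fraction
    gaps = np.where(
        is_transfer, 0, rng.integers(1, config.window_days + 1, size=n_follow)
    )
    f_entry = entry_off[spawn_idx] + los[spawn_idx] + gaps
    f_los = 2 + rng.poisson(config.followup_los_mean, size=n_follow)
    short = is_transfer & (rng.random(n_follow) < config.short_transfer_fraction)
    f_los[short] = rng.integers(0, 2, size=int(short.sum()))
    f_domains = np.empty(n_follow, dtype=np.int64)
    for h in np.unique(to_hosp):
        mask = to_hosp == h
        f_domains[mask] = rng.choice(config.n_domains, size=int(mask.sum()), p=profiles[h])

    # --- assemble --------------------------------------------------------
    all_hosp = np.concatenate([hosp_idx, to_hosp])
    all_entry = np.concatenate([entry_off, f_entry])
    all_los = np.concatenate([los, f_los])
    all_domain = np.concatenate([domains, f_domains])
    all_patient = np.concatenate([patient_ids, patient_ids[spawn_idx]])
    n_all = all_hosp.size

    valid = rng.random(n_all) >= config.invalid_fraction
    iterative = rng.random(n_all) < config.iterative_fraction

    stays = pd.DataFrame(
        {
            "patient_id": all_patient,
            "hospital_id": hospital_ids[all_hosp],
            "entry_date": year0 + all_entry.astype("timedelta64[D]"),
            "discharge_date": year0 + (all_entry + all_los).astype("timedelta64[D]"),
            "activity_domain": np.char.add("AD", all_domain.astype(str)),
            "valid": valid,
            "iterative_treatment": iterative,
        }
    )
    stays["entry_date"] = pd.to_datetime(stays["entry_date"])
    stays["discharge_date"] = pd.to_datetime(stays["discharge_date"])
    return stays, registry, truth


def reference_config(
    volume_scale: float = 1.0,
    hospitals: tuple[int, int, int] = (34, 236, 157),
    seed: int = 0,
    **overrides,
) -> SynthConfig:
    """The three-archetype configuration emulating the 2016 study system.

    Archetype medians, diversity means/SDs, mobility rates and the referral
    mix come from the study's printed profile and flow tables; log-normal
    dispersions are fitted to the printed interquartile ranges.
    ``volume_scale`` scales all volume medians jointly (ratios preserved) so
    the full pipeline can be run at reduced size; ``hospitals`` sets the
    number of hospitals per archetype (large, medium, small).  The number of
    regional groups tracks the hospital count (about three hospitals per
    group, as in the real system) unless overridden.
    """
    n1, n2, n3 = hospitals
    overrides.setdefault(
        "n_regional_groups", max(2, round((n1 + n2 + n3) * 136 / 427))
    )
    # log-sd from IQR: sigma = ln(Q3/Q1) / (2 * 0.6745)
    specs = [
        ArchetypeSpec(
            name="G1",
            n_hospitals=n1,
            mean_annual_stays=82_108 * volume_scale,
            stay_dispersion=0.396,
            effective_domains=15.86,
            effective_domains_sd=0.60,
            target_mobility_rate=0.02,
            referral_mix=published.REFERRAL_MIX["G1"],
        ),
        ArchetypeSpec(
            name="G2",
            n_hospitals=n2,
            mean_annual_stays=18_913 * volume_scale,
            stay_dispersion=0.567,
            effective_domains=12.26,
            effective_domains_sd=0.70,
            target_mobility_rate=0.04,
            referral_mix=published.REFERRAL_MIX["G2"],
        ),
        ArchetypeSpec(
            name="G3",
            n_hospitals=n3,
            mean_annual_stays=2_337 * volume_scale,
            stay_dispersion=1.102,
            effective_domains=8.63,
            effective_domains_sd=0.80,
            target_mobility_rate=0.11,
            referral_mix=published.REFERRAL_MIX["G3"],
        ),
    ]
    return SynthConfig(archetypes=specs, seed=seed, **overrides)


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """A copy of the config with a different seed."""
    return replace(config, seed=seed)
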