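# Methods

`hospiflow` profiles the hospitals of a national system from one year of
discharge records and analyzes the inter-hospital patient-flow network.
This note documents the model, the synthetic data the package is validated
on, and the numerical and design choices a maintainer should know about.

## The analysis

### Inclusion rules

Starting from a stay table (one row per hospital stay) and a hospital
registry, stays are filtered in a fixed order:

1. stays failing quality control (`valid = false`) and stays for iterative
   treatments are dropped;
2. stays at hospitals flagged for exclusion in the registry (overseas
   groups, psychiatric-only groups, single multi-site legal entities) are
   dropped;
3. received *transfers* — stays beginning on the day the same patient was
   discharged from a different hospital — are dropped when their own length
   of stay is under 48 h. The source schema carries dates, not times, so
   length of stay is `24 h × (discharge − entry)` and "< 48 h" means a date
   difference of 0 or 1 day;
4. hospitals whose remaining volume is below 500 stays/year are dropped,
   with the volume counted *after* the other filters.

The order of rules 3 and 4 is not dictated by the problem; recomputing
volume after the other removals reads the volume floor as a criterion on
retained activity, and the choice is tested (the filter is idempotent and
the exclusion ledger is conservative: rows in = rows out + ledger total).

### Mobility events

For every index stay, the *earliest* subsequent stay of the same patient in
a different hospital whose entry falls within 90 days of the index
discharge generates one mobility event. Gap 0 (entry on the discharge day)
is a transfer; positive gaps are readmissions. One event per index stay —
an A→B→C chain counts as A→B plus B→C, never A→C — because the quantity of
interest is "was this stay followed by care elsewhere", a property of the
index stay. An all-pairs mode is exposed for sensitivity analysis. Ties on
the entry date are broken by receiving-hospital id; a subsequent stay that
*overlaps* the index stay (entry before the index discharge, in a different
hospital) is contradictory in discharge data, suppresses the event, and is
counted in a diagnostics report. The window is measured discharge-to-entry
in whole days. No censoring correction is applied for stays discharged
within 90 days of the end of the extraction year; the count of such stays
is reported in the diagnostics.

### Hospital features

Three active variables per hospital:

* **volume** — annual stay count;
* **effective diversity** — the inverse-Simpson index (Hill number of order
  2) of the hospital's distribution over ~25 activity domains,
  `D = 1 / Σ p_i²`. D equals the number of practiced domains when they are
  equally frequent, is insensitive to rarely-practiced domains (500/3/2
  stays across three domains gives D ≈ 1.02), and is scale-invariant. It is
  preferred over the raw domain count, which saturates at its ceiling for
  every mid-size hospital;
* **mobility index** — the percentage of stays followed within 90 days by a
  stay in another hospital of the *same regional hospital group*.

Variables are z-scored (sample SD, `ddof = 1`; the convention is recorded in
the run metadata) and unweighted.

### Clustering

K-means (Lloyd), best of `n_restarts` initializations by within-cluster sum
of squares (WSS). Initialization is k-means++ by default — plain random
seeding, closer to the textbook description, is available via config; with
tens of restarts the two agree on this data. The number of clusters is
chosen by majority vote of four internal validity indices over k = 2…8 —
silhouette and Calinski-Harabasz (maximize), Davies-Bouldin (minimize), and
Hartigan's statistic `H(k) = (W_k/W_{k+1} − 1)(n − k − 1)` — and verified
against the WSS elbow. Hartigan's classical stopping rule (first k with
H ≤ 10) never fires on low-dimensional continuous data, where splitting any
cluster keeps cutting WSS by more than the threshold's implied fraction;
when no k qualifies, the index votes for the largest drop of the statistic
(its elbow) instead. Ties break toward smaller k
(parsimony). A four-index suite replaces the thirty-index batteries found
in R packages; the majority-plus-elbow logic is what carries the
conclusion, and the four indices cover the three main families
(separation/cohesion ratio, variance ratio, successive-improvement).

### Network analysis

Mobility events aggregate into a directed weighted graph (hospitals =
vertices, edge weight = patients sent). Two views: *all* edges, and
*strong* edges, keeping a hospital pair iff it exchanged at least 100
patients in either direction (both directed edges of a qualifying pair are
retained). Degree assortativity (Newman's degree-degree Pearson
correlation) and global transitivity (3 × triangles / connected triples)
are computed on the undirected simple graph underlying each view — the
strong-edge rule is itself direction-agnostic, and the undirected variants
are the ones with clean closed-form behavior on reference graphs (star:
r = −1, t = 0). A directed (out, in) assortativity is emitted alongside as
metadata. Edge density uses the directed denominator `m / (n(n−1))`.
Assortativity is undefined on degree-regular graphs (cycles, complete
graphs) and is reported as NaN with a flag, never silently as a number.
Inter-cluster flows are tabulated as a k×k matrix with row percentages
(share of the sending cluster's mobility) and overall percentages (share of
all mobility), the display rounding matching the printed convention (whole
percent).

### Sensitivity

Omitting one active variable and refitting at the same k measures how much
the partition depends on it. Cluster labels are arbitrary, so disagreement
is minimized over label permutations (Hungarian matching) before being
reported as a percentage of hospitals changing cluster.

## The synthetic generator

The real claims database is access-restricted, so the package validates
against a generator that plants the structure the analysis is supposed to
find: three hospital archetypes — large reference centers (G1), medium
general hospitals (G2), small local hospitals (G3) — with an asymmetric
referral flow directed up the tiers, inside a system of regional groups of
about three hospitals each.

Defaults mirror the published description of the 2016 French public-hospital
system wherever a number is printed: 34/236/157 hospitals per archetype;
volume medians 82,108 / 18,913 / 2,337 stays with log-normal dispersions
fitted to the printed interquartile ranges (σ = 0.396 / 0.567 / 1.102);
mean effective diversities 15.86 / 12.26 / 8.63 over 25 activity domains;
overall mobility rates 2 % / 4 % / 11 %; a referral mix taken from the
printed inter-cluster flow shares; 45.5 % of referrals sought within the
sender's regional group; 43.6 % of follow-ups entering on the discharge day
(transfers). Per-hospital domain profiles are built by solving a geometric
base profile for the hospital's exact target inverse-Simpson value and
perturbing it with a tight Dirichlet draw. Bed counts scale with volume
(≈ 73 stays/bed). Follow-up stays get lengths of stay ≥ 2 days so they
survive the 48-h transfer filter; a configurable fraction of sub-48-h
transfers can be injected to exercise that rule (default 0).

Where the source prints no number, the choice is a documented stand-in:

* **Latent dispersions.** The printed per-group SDs describe the *fitted*
  partition of the real data, not latent archetypes; a generator using them
  as archetype noise plants structure that is not statistically
  identifiable, which would make recovery tests meaningless. The latent
  between-hospital SDs are instead set so that adjacent archetypes sit
  several standard deviations apart on at least one variable (diversity SDs
  0.6 / 0.7 / 0.8; per-hospital mobility rates jittered log-normally with
  σ = 0.25), i.e. the planted structure is *well separated*: a quadratic
  classifier on the true labels reaches ≈ 99 % accuracy. Recovery tests
  therefore measure pipeline correctness, not the (unknowable) noise level
  of the real system.
* **Distributional forms** (log-normal volumes, Poisson lengths of stay,
  uniform entry dates, uniform readmission gaps after the transfer mass at
  gap 0) are plausibility choices; nothing downstream depends on them
  beyond their first two moments.
* **Regional-group geometry**: hospitals are interleaved across groups so
  most groups mix tiers; the group count tracks the hospital count at ~3
  hospitals/group. The same-group/out-of-group decision for each referral is
  primary (so the realized within-group share tracks the alignment
  parameter), with the referral-mix archetype preferred within that choice.

What the generator does **not** emulate: geography and distance (referrals
are distance-blind), seasonality, patient-level case mix and severity,
correlated multi-stay trajectories beyond one follow-up per index stay, and
year-boundary effects beyond simple truncation. Passing recovery tests
therefore shows the pipeline recovers planted volume/diversity/mobility
structure — not that real hospital systems are this clean.

## Problem sizes and numerics

* The reference validation runs the generator at half the study's data
  volume (~4.6 M stays, 427 hospitals) with the two absolute-count
  thresholds (500-stay floor, 100-patient strong edge) scaled jointly,
  preserving the study geometry within a memory- and minutes-scale budget;
  archetype recovery is summarized as the mean adjusted Rand index over
  three replicate systems. Replicate checks that only need the majority
  rule (k = 3 across ten seeds) run at a tenth of the volume. Scaled runs
  behave identically apart from larger estimation noise on small hospitals.
* K-means: tolerance 1e-6 on centroid shift, 300 iterations max, 20–50
  restarts. WSS is recomputable from the persisted assignments and
  centroids, and the k = 3 solution is verified against exhaustive
  partition search on small instances.
* The inverse-Simpson solver brackets the geometric ratio in (0, 1) and is
  exact to 1e-13; degenerate targets (1 or the domain count) short-circuit
  to the closed forms.
* Quantiles use linear interpolation (the default of the surrounding
  ecosystem); the convention is switchable where it matters (profiles).
* Standardization refuses zero-variance columns by name rather than
  emitting NaNs.
* Reports are deterministic: rendering the same run directory twice is
  byte-identical.

## Known limitations

* The mobility index couples the within-group share to group geometry; in
  scaled runs with few hospitals per group the realized index sits below
  the archetype's nominal rate (fewer eligible same-group targets). Only
  its ordering across archetypes is load-bearing.
* Adjusted-Rand recovery of the planted archetypes is limited by k-means
  itself (spherical, equal-variance boundaries on elongated clusters), not
  by the planted separation; a covariance-aware classifier on the same
  features is near-perfect. ARI lands around 0.87–0.95 per replicate at
  half volume, ≥ 0.9 on average.
* `detect_mobility` loops over patients with ≥ 2 stays in Python; fine up
  to ~10 M stays, but a candidate for vectorization if the package is ever
  pointed at a multi-year extraction.
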