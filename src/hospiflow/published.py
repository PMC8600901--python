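"""Published summary tables of the 2016 French public-hospital study.

These are *inputs*: aggregated counts printed in the study this package
re-implements. They are used to exercise the percentage / flow-matrix
arithmetic on real numbers and to parameterize the synthetic generator
(volume medians, effective-diversity targets, referral mix). The underlying
stay-level database is access-restricted and is never shipped here.
"""

from __future__ import annotations

import pandas as pd

CLUSTERS = ("G1", "G2", "G3")

#: Cluster sizes (number of hospitals) of the three profiles.
CLUSTER_SIZES = {"G1": 34, "G2": 236, "G3": 157}

#: Median [Q1, Q3] annual stays per hospital, by profile.
STAYS_QUARTILES = {
    "G1": (82_108, 69_004, 117_774),
    "G2": (18_913, 12_410, 26_689),
    "G3": (2_337, 1_195, 5_285),
}

#: Mean (SD) of the same-group mobility index, in percent.
MOBILITY_MEAN_SD = {"G1": (2.0, 1.0), "G2": (4.0, 2.0), "G3": (11.0, 5.0)}

#: Mean (SD) of the effective number of activity domains.
EFFECTIVE_DOMAINS_MEAN_SD = {"G1": (15.86, 0.70), "G2": (12.26, 1.72), "G3": (8.63, 2.73)}

#: Mean (SD) of the absolute number of activity domains.
ABSOLUTE_DOMAINS_MEAN_SD = {"G1": (24.74, 0.45), "G2": (23.61, 1.01), "G3": (19.94, 3.65)}

_DOMAIN_ROWS = [
    # domain, G1, G2, G3
    ("Digestive system", 371_553, 728_168, 105_647),
    ("Orthopaedics, trauma care", 218_590, 354_687, 43_024),
    ("Complex trauma", 5_663, 2_835, 249),
    ("Diseases of the bone and joint", 103_486, 109_229, 17_433),
    ("Diseases of the nervous system", 331_825, 317_859, 38_435),
    ("Diagnostic and therapeutic vascular catheterisms", 127_284, 104_315, 544),
    ("Cardiovascular medicine", 244_072, 392_896, 65_098),
    ("Pulmonology", 218_533, 363_264, 52_243),
    ("Ear, nose and throat. Oral medicine", 124_211, 171_502, 14_636),
    ("Ophtalmology", 107_057, 114_451, 11_575),
    ("Gynecology - breast diseases", 80_690, 101_535, 7_172),
    ("Obstetrics", 217_830, 467_071, 39_593),
    ("Newborns, perinatal period", 132_451, 302_957, 23_298),
    ("Urology, nephrology, male genital system", 200_518, 270_610, 30_623),
    ("Hematology", 95_755, 97_065, 13_219),
    ("Chemotherapy, radiotherapy, excluding iterative treatments", 70_488, 40_885, 1_797),
    ("Infectious disease (including HIV)", 35_028, 47_911, 4_548),
    ("Endocrinology", 125_642, 139_507, 14_769),
    ("Skin and subcutaneous tissue", 87_844, 105_833, 14_389),
    ("Burns", 6_161, 2_197, 214),
    ("Psychiatry", 88_586, 110_198, 21_941),
    ("Toxicology, alcohol-related disease", 82_024, 153_170, 33_064),
    ("Chronic pain, palliative care", 37_994, 48_723, 8_779),
    ("Organ transplantation", 3_844, 1, 0),
    ("Transversal disease management and follow-up", 257_172, 266_162, 37_567),
]

#: Per-cluster stay counts by activity domain (25 domains x 3 profiles).
ACTIVITY_DOMAIN_COUNTS = pd.DataFrame(
    [(r[1], r[2], r[3]) for r in _DOMAIN_ROWS],
    index=pd.Index([r[0] for r in _DOMAIN_ROWS], name="activity_domain"),
    columns=list(CLUSTERS),
)

#: Inter-cluster mobility event counts: index = sending cluster, columns = receiving.
FLOW_COUNTS = pd.DataFrame(
    [
        [22_665, 79_928, 20_650],
        [118_601, 84_322, 26_573],
        [25_687, 29_688, 6_140],
    ],
    index=pd.Index(list(CLUSTERS), name="from_cluster"),
    columns=pd.Index(list(CLUSTERS), name="to_cluster"),
)

#: Row percentages of the flow table as printed (percent of departure group).
FLOW_ROW_PCT_PRINTED = pd.DataFrame(
    [[18, 65, 17], [52, 37, 12], [42, 48, 10]],
    index=FLOW_COUNTS.index,
    columns=FLOW_COUNTS.columns,
)

#: Referral mix used by the synthetic generator: where outgoing mobility goes,
#: as fractions, derived from the flow table's row percentages.
REFERRAL_MIX = {
    "G1": {"G1": 0.18, "G2": 0.65, "G3": 0.17},
    "G2": {"G1": 0.52, "G2": 0.37, "G3": 0.11},
    "G3": {"G1": 0.42, "G2": 0.48, "G3": 0.10},
}
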