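"""Published SEER 2000-2020 colorectal adenocarcinoma cohort counts.

These are the printed summary counts of a published national-registry
cohort of 309,466 colorectal adenocarcinoma patients: for each demographic
or clinical factor level, the number of tumors in sigmoidoscopy-
visualizable subsites and the level total; and the subsite-by-age-group
count grid for the nine analyzed subsites.  They are inputs to the
table-replication entry points (``sigreach.report.replicate_tables``),
which recompute proportions and odds ratios from the raw counts at run
time — no derived statistic is stored here.
"""

from __future__ import annotations

__all__ = [
    "COHORT_N",
    "TABLE1_FACTORS",
    "SUBSITE_AGE_COUNTS",
    "AGE_GROUP_ORDER",
]

#: Total cohort size after exclusions.
COHORT_N = 309_466

#: Per factor: ordered {level: (n_visualizable, n_total)}; first level is
#: the reference level of the logistic models.
TABLE1_FACTORS: dict[str, dict[str, tuple[int, int]]] = {
    "age_group": {
        "50plus": (151_015, 269_861),
        "45to49": (13_922, 18_906),
        "under45": (15_049, 20_699),
    },
    "sex": {
        "female": (78_119, 148_136),
        "male": (101_867, 161_330),
    },
    "stage": {
        "localized": (54_769, 96_974),
        "regional": (77_596, 134_694),
        "distant": (47_621, 77_798),
    },
    "race_ethnicity": {
        "NH-White": (117_647, 206_185),
        "Hispanic": (23_089, 36_736),
        "NH-AIAN": (1_481, 2_394),
        "NH-API": (19_070, 28_041),
        "NH-Black": (18_018, 35_067),
        "NH-Unknown": (681, 1_043),
    },
    "year_group": {
        "2000-2004": (38_201, 66_774),
        "2005-2009": (39_821, 69_575),
        "2010-2014": (40_625, 70_071),
        "2015-2020": (61_339, 103_046),
    },
}

AGE_GROUP_ORDER = ("under45", "45to49", "50plus")

#: Subsite x age-group counts, keyed by topography code; columns follow
#: AGE_GROUP_ORDER.
SUBSITE_AGE_COUNTS: dict[str, tuple[int, int, int]] = {
    "C209": (6_152, 5_807, 56_988),   # Rectum
    "C199": (2_333, 2_186, 23_762),   # Rectosigmoid Junction
    "C187": (5_380, 4_976, 58_308),   # Sigmoid
    "C186": (1_184, 953, 11_957),     # Descending Colon
    "C185": (571, 443, 6_922),        # Splenic Flexure
    "C184": (1_146, 878, 18_595),     # Transverse Colon
    "C183": (563, 418, 9_887),        # Hepatic Flexure
    "C182": (1_615, 1_493, 38_933),   # Ascending Colon
    "C180": (1_755, 1_752, 44_509),   # Cecum
}
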