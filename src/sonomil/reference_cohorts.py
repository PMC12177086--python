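"""Published clinical-characteristic counts of the three study cohorts.

The tool was developed against a retrospective three-cohort breast-cancer
study (training n=1144, internal test n=273, external test n=140). The
raw images are private, but the cohort characteristic tables and ALN
prevalences are public; they serve as canonical inputs for the
chi-square cohort-comparison utilities and for prevalence bookkeeping.

Counts are ordered by the level tuples given alongside each table.
"""

from __future__ import annotations

COHORTS = ("training", "internal", "external")

# (ALN-positive count, cohort size)
ALN_PREVALENCE = {
    "training": (735, 1144),
    "internal": (184, 273),
    "external": (94, 140),
}

CHARACTERISTIC_LEVELS = {
    "clinical_t_stage": ("T1", "T2", "T3", "T4"),
    "birads": ("4A", "4B", "4C", "5"),
    "pathological_type": ("invasive_ductal", "invasive_lobular",
                          "mixed_with_in_situ", "other"),
    "er_status": ("positive", "negative"),
    "pr_status": ("positive", "negative"),
    "cerbb2_status": ("positive", "negative"),
    "ki67": ("1-10%", "11-50%", "51-100%"),
    "lymphovascular_invasion": ("yes", "no", "unknown"),
    "perineural_invasion": ("yes", "no", "unknown"),
}

CHARACTERISTIC_COUNTS = {
    "clinical_t_stage": {
        "training": (349, 697, 66, 32),
        "internal": (92, 164, 15, 2),
        "external": (55, 81, 4, 0),
    },
    "birads": {
        "training": (66, 227, 438, 413),
        "internal": (29, 51, 103, 90),
        "external": (19, 16, 70, 35),
    },
    "pathological_type": {
        "training": (924, 22, 171, 27),
        "internal": (233, 6, 25, 9),
        "external": (102, 5, 31, 2),
    },
    "er_status": {
        "training": (739, 405),
        "internal": (179, 94),
        "external": (109, 31),
    },
    "pr_status": {
        "training": (601, 543),
        "internal": (153, 120),
        "external": (102, 38),
    },
    "cerbb2_status": {
        "training": (405, 739),
        "internal": (85, 188),
        "external": (42, 98),
    },
    "ki67": {
        "training": (102, 776, 266),
        "internal": (34, 178, 61),
        "external": (5, 90, 45),
    },
    "lymphovascular_invasion": {
        "training": (279, 367, 498),
        "internal": (65, 87, 121),
        "external": (72, 46, 22),
    },
    "perineural_invasion": {
        "training": (85, 537, 522),
        "internal": (19, 126, 128),
        "external": (9, 73, 58),
    },
}


def contingency(characteristic: str, cohort_a: str, cohort_b: str):
    """2 x c table of a characteristic's counts in two cohorts."""
    counts = CHARACTERISTIC_COUNTS[characteristic]
    return [list(counts[cohort_a]), list(counts[cohort_b])]


def prevalence_percent(cohort: str) -> float:
    pos, n = ALN_PREVALENCE[cohort]
    return round(100.0 * pos / n, 1)
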