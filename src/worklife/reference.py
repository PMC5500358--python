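"""Published registry tabulations for the Norwegian male conscript cohort.

These are the printed summary tables from the national study this package
models (918 888 men born 1950-1980, benefit episodes observed 1992-2008).
The individual-level registry data are not public; the tabulations below are
used as arithmetic fixtures: the classification rules applied to the score
distributions must reproduce the published analysis-group sizes, and the
transition-count matrix must reproduce the published totals.
"""

from __future__ import annotations

import numpy as np

N_COHORT = 918_888

#: Conscription score distributions (counts per score value).  The military
#: scales run 1-9 with 9 = no impairment; 8 is never used, and categories 1
#: and 2 are published merged (category 2 had fewer than 5 observations per
#: variable).  Keys are score values; "1&2" is the merged low category.
SCORE_COUNTS: dict[str, dict[str, int]] = {
    "mental_health": {"1&2": 6660, "3": 6998, "4": 2755, "5": 2804,
                      "6": 5102, "7": 9561, "9": 576414, "missing": 308594},
    "physical_health": {"1&2": 10104, "3": 10300, "4": 7630, "5": 11060,
                        "6": 20638, "7": 33839, "9": 516700, "missing": 308617},
    "arm": {"1&2": 1009, "3": 6450, "4": 1069, "5": 1732,
            "6": 2888, "7": 4587, "9": 591358, "missing": 309795},
    "hand": {"1&2": 1082, "3": 6397, "4": 1136, "5": 1712,
             "6": 3065, "7": 4860, "9": 590846, "missing": 309790},
    "walking": {"1&2": 2335, "3": 7279, "4": 2702, "5": 5447,
                "6": 12383, "7": 27247, "9": 551814, "missing": 309681},
    "back": {"1&2": 2127, "3": 6940, "4": 2486, "5": 4583,
             "6": 13574, "7": 26440, "9": 553037, "missing": 309701},
    "skin": {"1&2": 1273, "3": 6427, "4": 2095, "5": 3130,
             "6": 6332, "7": 12671, "9": 577164, "missing": 309796},
}

#: STANINE general-ability (IQ) score distribution for men who took the
#: written test, and letter grades (A/B/C, assumed above/at/below average)
#: for men without a test.
STANINE_COUNTS: dict[int, int] = {
    1: 15_709, 2: 37_614, 3: 75_441, 4: 134_404, 5: 172_954,
    6: 163_404, 7: 125_059, 8: 75_018, 9: 38_555,
}
LETTER_COUNTS: dict[str, int] = {"C": 3_769, "B": 20_318, "A": 1_124}

#: Published combined IQ-category counts (low / average / high).
COMBINED_IQ_COUNTS: dict[str, int] = {
    "low": 57_092, "average": 691_580, "high": 114_697,
}

#: Published analysis-group sizes (the six state-probability panels).
GROUP_SIZES: dict[str, int] = {
    "iq_average_or_high": 806_277,
    "iq_low": 57_092,
    "mental_none": 576_414,
    "mental_problems": 33_880,
    "mental_none_iq_average_or_high": 518_852,
    "mental_problems_iq_low": 8_130,
}

#: Published transition-count matrix: rows are the seven transient states
#: (employment, sick leave, vocational rehab, medical rehab, time-limited
#: disability, disability, emigrated), columns are the eight destination
#: states followed by "alive and at risk" (right-censored at end of 2008).
TRANSITION_FROM_STATES = [1, 2, 3, 4, 5, 6, 7]
TRANSITION_TO_STATES = [1, 2, 3, 4, 5, 6, 7, 8]

TRANSITION_COUNTS = np.array(
    [
        #  1:emp    2:sick  3:voc   4:med   5:tld  6:dis   7:emi  8:dead  censored
        [      0, 1657895, 45865,  48607,  3736, 20314,  28421, 10860, 729891],
        [1595592,  133909, 53398,  48325,   559,  3309,    454,   726, 105714],
        [ 101605,     983,  2009,    962,  3816,  9351,    175,    85,    288],
        [  82070,     130,     0,  14381,  1320,  5164,     93,    81,  10566],
        [   1153,      68,   148,     84,     0,  7930,      7,    23,    191],
        [   7729,     307,    75,     26,    37,     0,   1404,   819,  45265],
        [  26487,     317,    32,     51,     0,    46,     53,    13,      5],
    ],
    dtype=np.int64,
)

#: Published column totals of the matrix above (destinations + censored).
TRANSITION_COLUMN_TOTALS = np.array(
    [1_814_636, 1_793_609, 101_527, 112_436, 9_468, 46_114, 30_607, 12_607,
     891_920],
    dtype=np.int64,
)

#: Published grand total of transitions (all destination cells, deaths
#: included, censoring excluded).
TOTAL_TRANSITIONS = 3_921_004
TOTAL_DEATHS = 12_607
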