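"""Published summary tables of the motivating cohort.

The package's synthetic cohorts emulate a study of 69 primary-school
children (39 typically developing, TD; 30 with suspected developmental
coordination disorder, sDCD) who wore wrist accelerometers for a week and
completed a motor-competence assessment.  The study deposited no raw data,
only group-level summaries; those summaries are recorded here verbatim and
serve two purposes:

* defaults for :class:`coda24.simulate.CohortSpec`, so generated cohorts
  reproduce the reported group compositional means, demographic margins and
  lifestyle contingency tables;
* self-checks of the package's arithmetic (closure/percentage identities,
  Pearson chi-square on the contingency tables) against the printed values.
"""

from __future__ import annotations

import numpy as np

#: part order of whole-day compositions
PARTS = ("sleep", "sb", "lpa", "mvpa")

#: reported group compositional means, minutes per day (sum 1440), by segment
GROUP_MEAN_MINUTES = {
    "total": {
        "td": (436.3, 691.7, 244.6, 67.4),
        "sdcd": (437.4, 735.6, 213.7, 53.3),
    },
    "weekday": {
        "td": (435.1, 683.5, 252.3, 69.1),
        "sdcd": (430.7, 736.1, 218.1, 55.1),
    },
    "weekend": {
        "td": (465.3, 699.6, 215.6, 59.5),
        "sdcd": (489.1, 706.4, 197.0, 47.5),
    },
}

#: reported percentages alongside the minutes above (percent of 1440)
GROUP_MEAN_PERCENT = {
    "total": {
        "td": (30.3, 48.0, 17.0, 4.7),
        "sdcd": (30.4, 51.1, 14.8, 3.7),
    },
    "weekday": {
        "td": (30.2, 47.5, 17.5, 4.8),
        "sdcd": (29.9, 51.1, 15.1, 3.8),
    },
    "weekend": {
        "td": (32.3, 48.6, 15.0, 4.1),
        "sdcd": (34.0, 49.1, 13.7, 3.3),
    },
}

#: reported school-time (08:45-15:15) compositional means, minutes (3-part).
#: NOTE: the published TD row sums to 411 min against the 390-min school day
#: and its LPA percentage is inconsistent with its minutes; it is recorded
#: as printed and is not used as a simulation target.
SCHOOL_MEAN_MINUTES = {
    "td": (246.5, 134.1, 30.4),
    "sdcd": (257.5, 104.6, 27.9),
}

#: cohort demographics
N_TD = 39
N_SDCD = 30
PROP_BOYS = 0.55
AGE_MEAN = 8.6
AGE_SD = 1.6
AGE_RANGE = (6.9, 11.4)
#: WIMD quartile counts for the full sample (one child unreported)
DEPRIVATION_COUNTS = (14, 35, 11, 8)

#: DCDQ screening thresholds: score strictly below the cut marks suspected
#: DCD.  Bands are (max exclusive age, threshold); ages past the last band
#: use the final threshold.  The instrument scores 0-75.
DCDQ_BANDS = ((8.0, 47), (10.0, 56))
DCDQ_MAX = 75
SFDC_MAX = 24.0

#: lifestyle questionnaire contingency tables, counts as (TD row, sDCD row),
#: with the reported chi-square p-value
LIFESTYLE_TABLES = {
    "active_transport": {
        "levels": ("yes", "no"),
        "td": (17, 18),
        "sdcd": (14, 12),
        "reported_p": 0.68,
    },
    "lunch_activity": {
        "levels": ("ran", "sat", "stood", "walked"),
        "td": (21, 5, 0, 9),
        "sdcd": (16, 0, 2, 8),
        "reported_p": 0.09,
    },
    "friends_at_lunch": {
        "levels": ("alone", "1-2", "3-4", "5+"),
        "td": (1, 8, 15, 11),
        "sdcd": (6, 9, 3, 8),
        "reported_p": 0.01,
    },
    "sports_club": {
        "levels": ("0", "1-4", "5+"),
        "td": (7, 21, 6),
        "sdcd": (15, 9, 2),
        "reported_p": 0.01,
    },
}


def lifestyle_counts(name: str) -> np.ndarray:
    """The 2 x c count table (rows TD, sDCD) for a lifestyle item."""
    t = LIFESTYLE_TABLES[name]
    return np.array([t["td"], t["sdcd"]], dtype=int)


def dcdq_threshold(age: float) -> int:
    for max_age, thr in DCDQ_BANDS:
        if age < max_age:
            return thr
    return DCDQ_BANDS[-1][1]


#: outcome-model coefficients used as generator defaults.  ilr slopes are in
#: the sleep-pivot basis over (sleep, sb, lpa, mvpa); they are calibrated so
#: that, at the cohort reference composition, reallocating 5 min from LPA to
#: MVPA raises predicted motor competence by ~0.56 score units, matching the
#: strength of association the motivating study reported.
DEFAULT_OUTCOME_COEFFICIENTS = {
    "intercept": 18.5,
    "z1": -1.56,
    "z2": -2.21,
    "z3": -6.78,
    "age": 0.5,
    "sex_male": 0.3,
    "deprivation": -0.2,
}
#: residual SD of the motor-competence score (score units).  Together with
#: the default log-ratio dispersion of 0.25 this reproduces the reported
#: model R^2 (~0.15) and the reported width of the 5-min reallocation CI
#: (half-width ~0.4 score units at n = 69).
DEFAULT_OUTCOME_NOISE_SD = 5.0
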