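"""Canonical design of the adolescent cannabis-use survey this package models.

The questionnaire follows a widely fielded school-survey template: one
ordinal outcome (past-30-day cannabis-use frequency on a 7-point scale),
two individual variables (gender, age 15-17), and five multi-item
constructs measuring school disengagement, parental monitoring,
religiousness, parental tolerance of substance use, and substance use by
peers.  The constants below encode that structure — item inventories,
Likert ranges, reference marginal response frequencies from a large urban
Spanish school sample, published calibration anchors, and the directional
hypotheses used for intermediate fsQCA solutions — so that synthetic data
and default analysis settings reproduce the study's conditions.
"""

from __future__ import annotations

OUTCOME = "USE"
GENDER = "GENDER"
AGE = "AGE"

#: Construct name -> (number of items, Likert minimum, Likert maximum).
CONSTRUCT_DESIGN: dict[str, tuple[int, int, int]] = {
    "DSCHOOL": (10, 1, 5),
    "MONITOR": (11, 1, 4),
    "RELIGION": (12, 1, 4),
    "P_TOLER": (3, 1, 4),
    "PEER_USE": (5, 1, 5),
}

#: All seven causal conditions, in canonical order.
CONDITIONS: tuple[str, ...] = (
    GENDER, AGE, "DSCHOOL", "MONITOR", "RELIGION", "P_TOLER", "PEER_USE",
)

#: Outcome codes 1..7 ("never" .. "40 times or more").
OUTCOME_CATEGORIES = tuple(range(1, 8))

#: Age codes and their set memberships (15 -> 0, 16 -> 0.5, 17 -> 1).
AGE_CODES = (15, 16, 17)


def construct_items(name: str) -> list[str]:
    """Item column names for a construct, e.g. ``MONITOR1`` .. ``MONITOR11``."""
    k, _, _ = CONSTRUCT_DESIGN[name]
    return [f"{name}{i}" for i in range(1, k + 1)]


def default_construct_map() -> dict[str, list[str]]:
    return {name: construct_items(name) for name in CONSTRUCT_DESIGN}


#: Theoretical item-sum ranges implied by the Likert bounds.
SCORE_RANGES: dict[str, tuple[int, int]] = {
    name: (k * lo, k * hi) for name, (k, lo, hi) in CONSTRUCT_DESIGN.items()
}

#: Published 10th/50th/90th percentile calibration anchors for the item sums.
#: P_TOLER's anchors are degenerate (q10 == q50): in the reference sample more
#: than half the respondents sat at the scale floor.
REFERENCE_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "DSCHOOL": (28.0, 39.0, 45.0),
    "MONITOR": (15.0, 22.0, 29.0),
    "RELIGION": (12.0, 17.0, 34.0),
    "P_TOLER": (3.0, 3.0, 9.0),
    "PEER_USE": (5.0, 11.0, 18.0),
}

#: Reference marginal response frequencies (percent) per item and category.
#: Rows need not sum exactly to 100 (printed rounding).
REFERENCE_MARGINALS: dict[str, tuple[float, ...]] = {
    "USE": (72.52, 8.14, 4.51, 3.08, 3.30, 2.31, 6.27),
    "DSCHOOL1": (31.64, 27.51, 25.54, 10.55, 4.86),
    "DSCHOOL2": (12.93, 25.03, 31.44, 19.23, 11.48),
    "DSCHOOL3": (36.14, 29.91, 18.90, 9.24, 5.82),
    "DSCHOOL4": (15.85, 21.76, 28.08, 21.04, 13.16),
    "DSCHOOL5": (29.91, 32.92, 24.51, 8.83, 3.95),
    "DSCHOOL6": (15.22, 27.02, 33.23, 17.81, 6.73),
    "DSCHOOL7": (60.29, 16.84, 11.12, 6.76, 4.99),
    "DSCHOOL8": (71.01, 11.16, 8.34, 4.59, 5.01),
    "DSCHOOL9": (66.11, 11.95, 9.25, 5.51, 7.28),
    "DSCHOOL10": (50.00, 27.12, 13.35, 5.49, 4.04),
    "MONITOR1": (0.83, 2.17, 19.36, 77.74),
    "MONITOR2": (3.73, 16.08, 46.58, 33.71),
    "MONITOR3": (6.28, 19.98, 43.72, 29.92),
    "MONITOR4": (6.35, 17.27, 37.25, 39.02),
    "MONITOR5": (3.55, 8.45, 27.11, 60.79),
    "MONITOR6": (2.71, 7.72, 24.43, 65.03),
    "MONITOR7": (2.40, 8.85, 35.73, 53.02),
    "MONITOR8": (8.86, 26.28, 40.46, 24.40),
    "MONITOR9": (20.31, 31.25, 33.54, 14.90),
    "MONITOR10": (36.29, 32.53, 20.75, 10.43),
    "MONITOR11": (19.90, 29.06, 33.44, 17.60),
    "RELIGION1": (54.20, 16.47, 13.09, 16.25),
    "RELIGION2": (47.70, 18.42, 14.58, 19.30),
    "RELIGION3": (69.79, 14.44, 7.28, 8.60),
    "RELIGION4": (79.25, 9.55, 6.04, 5.16),
    "RELIGION5": (76.75, 11.07, 5.70, 6.47),
    "RELIGION6": (77.23, 11.77, 5.17, 5.83),
    "RELIGION7": (63.77, 13.77, 11.67, 10.68),
    "RELIGION8": (57.87, 15.84, 13.31, 12.98),
    "RELIGION9": (54.25, 27.40, 12.27, 6.08),
    "RELIGION10": (45.25, 27.92, 19.09, 7.84),
    "RELIGION11": (48.06, 15.50, 15.39, 21.15),
    "RELIGION12": (55.11, 14.33, 14.11, 16.44),
    "P_TOLER1": (65.59, 17.48, 11.47, 5.35),
    "P_TOLER2": (47.53, 20.52, 23.09, 8.86),
    "P_TOLER3": (82.94, 10.89, 4.04, 2.13),
    "PEER_USE1": (25.93, 25.37, 27.73, 14.32, 6.65),
    "PEER_USE2": (17.70, 16.80, 23.56, 25.37, 16.57),
    "PEER_USE3": (28.44, 23.14, 24.60, 15.24, 8.47),
    "PEER_USE4": (41.08, 25.96, 18.51, 8.92, 5.53),
    "PEER_USE5": (67.65, 19.68, 8.82, 2.15, 1.70),
}

#: Directional hypotheses for intermediate-solution counterfactuals, stated
#: for the USE outcome: which state of each condition is expected to
#: contribute to cannabis use.  Being female protects, so the *absence* of
#: GENDER (male) contributes to use; older age, school disengagement -> use
#: runs through presence; monitoring and religiousness protect; parental
#: tolerance and peer use enable.
DEFAULT_EXPECTATIONS: dict[str, str] = {
    GENDER: "absent",
    AGE: "present",
    "DSCHOOL": "present",
    "MONITOR": "absent",
    "RELIGION": "absent",
    "P_TOLER": "present",
    "PEER_USE": "present",
}

#: Reference ordered-logit effects (log odds-ratio scale) of the calibrated
#: conditions on the outcome, used as the synthetic generator's default
#: effect structure: female, monitoring and religiousness inhibit use;
#: parental tolerance and peer use enable it.
REFERENCE_OLR_COEFFICIENTS: dict[str, float] = {
    GENDER: -0.960,
    AGE: 0.155,
    "DSCHOOL": -0.281,
    "MONITOR": -0.533,
    "RELIGION": -0.742,
    "P_TOLER": 3.738,
    "PEER_USE": 1.723,
}

#: Reference scale reliabilities (Cronbach's alpha) of the five constructs.
REFERENCE_ALPHAS: dict[str, float] = {
    "DSCHOOL": 0.769,
    "MONITOR": 0.799,
    "RELIGION": 0.928,
    "P_TOLER": 0.753,
    "PEER_USE": 0.884,
}

#: Output membership map for the 7-category use outcome:
#: 1 ("never") -> 0; 2 ("1-2 times") -> 0.2; 3 -> 0.8; 4 -> 0.9; >=5 -> 1.
DEFAULT_OUTCOME_MAP: dict[int, float] = {
    1: 0.0, 2: 0.2, 3: 0.8, 4: 0.9, 5: 1.0, 6: 1.0, 7: 1.0,
}

#: Sample composition of the reference survey (n = 1935 respondents).
REFERENCE_N = 1935
REFERENCE_FEMALE_PROPORTION = 0.537  # among respondents reporting gender
REFERENCE_AGE_DISTRIBUTION = (0.543, 0.288, 0.169)  # ages 15 / 16 / 17
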