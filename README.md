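# likertqca

Fuzzy-set qualitative comparative analysis (fsQCA) and proportional-odds
ordered logistic regression for Likert survey data, built around the study
design of a school survey on adolescent cannabis use.

## The problem

Surveys of adolescent substance use typically explain an ordinal outcome —
how often a respondent used cannabis in the last 30 days, on a 7-point
scale from "never" to "40 times or more" — with a mix of individual
variables (gender, age) and multi-item constructs: disengagement from
school (DSCHOOL), parental monitoring (MONITOR), religiousness (RELIGION),
parental tolerance of substance use (P_TOLER) and substance use by peers
(PEER_USE). Regression answers the *variable-oriented* question (what is
the average effect of each factor), but not the *case-oriented* one: which
combinations of factors — risk and protection *profiles* — are
consistently associated with use, and which with non-use? fsQCA answers
the second question, and this package runs both analyses side by side on
the same calibrated data.

It is aimed at public-health and social-science researchers who want a
reproducible, scriptable version of the common fsQCA desktop workflow
(truth table → Quine–McCluskey → complex/parsimonious/intermediate
solutions) integrated with scale validation and ordered regression, plus a
synthetic-data generator emulating the survey design so every stage can be
tested without access to restricted survey microdata.

## The method

**Calibration.** Construct item sums `x` are mapped to set memberships by
the percentile-anchored piecewise function

```
m(x) = 0                              x ≤ q10
     = (x − q10) / (2 (q50 − q10))    q10 < x ≤ q50
     = 0.5 + (x − q50) / (2 (q90 − q50))   q50 < x ≤ q90
     = 1                              x > q90
```

with anchors at the 10th/50th/90th percentiles of the retained sample (or
injected published anchors). Gender is calibrated 0/1 (male/female), age
15/16/17 → 0/0.5/1, and the outcome through the fixed map
{1→0, 2→0.2, 3→0.8, 4→0.9, ≥5→1}; negation is `m~X = 1 − mX`.

**Screening.** Each condition is cross-tabulated against the outcome over
quintile bins; Phi = √(χ²/n) and Kendall's tau-b summarize the
association, and Phi² < 0.5 flags enough "contrarian" (off-diagonal) cases
to justify the configurational analysis.

**Regression.** A proportional-odds model
`P(y ≤ j | x) = logistic(κⱼ − x'β)` is fitted by maximum likelihood, with
odds ratios, z-ratios, 95% CIs, the likelihood-ratio test and McFadden's
pseudo-R² against the cutpoints-only null.

**fsQCA.** A recipe `Z = X1*X2*…` has membership
`mZ = min(mX1, mX2, …)`, and is scored by

```
Cons(Z → Y) = Σ min(mZ, mY) / Σ mZ     (sufficiency consistency)
Cov(Z → Y)  = Σ min(mZ, mY) / Σ mY     (empirical coverage)
```

The 2^k truth-table rows are classified positive / negative / remainder
(frequency cutoff 1 case, consistency cutoff 0.8 by default) and minimized
with Quine–McCluskey (exact minimal cover: fewest recipes, then fewest
literals). The complex solution uses no remainders, the parsimonious
solution uses all of them, and the intermediate solution re-specializes
parsimonious recipes with the expectation-consistent literals of the
complex recipes they subsume, given directional expectations for each
condition. Use and non-use are analyzed independently.

## Worked example

```python
import likertqca as lq
from likertqca.config import StudyConfig, reference_generator_config

cfg = StudyConfig(
    generator=reference_generator_config(n_respondents=1935, seed=11,
                                         missingness_rate=0.0025),
    crossover_epsilon=0.001, seed=11,
)
report = lq.run_pipeline(cfg)
print(report.scores.n_retained)          # 1735 of 1935 after listwise deletion
print(report.alphas.round(3).to_dict())
# {'DSCHOOL': 0.759, 'MONITOR': 0.787, 'RELIGION': 0.919,
#  'P_TOLER': 0.734, 'PEER_USE': 0.886}       all constructs clear alpha > 0.7

from likertqca.ordered_logit import olr_report_text
print(olr_report_text(report.olr))
```

```
Predictor         OR    log OR       SE        z         p        95% CI (OR)
GENDER         0.516    -0.663    0.142   -4.661    0.0000     [0.390, 0.681]
AGE            1.052     0.051    0.179    0.284    0.7761     [0.741, 1.493]
DSCHOOL        0.454    -0.790    0.222   -3.559    0.0004     [0.294, 0.701]
MONITOR        0.324    -1.127    0.220   -5.116    0.0000     [0.210, 0.499]
RELIGION       0.255    -1.365    0.212   -6.442    0.0000     [0.169, 0.387]
P_TOLER     3269.572     8.092    0.386   20.959    0.0000 [1534.059, 6968.508]
PEER_USE      33.130     3.500    0.241   14.541    0.0000   [20.669, 53.105]
LR ratio = 1332.43 (p = 1.608e-283)
McFadden pseudo R^2 = 39.27%
```

Odds ratios are per unit of *membership* (the full sweep of a condition
from fully out to fully in its set), so protective factors sit below 1
(being female, monitoring, religiousness) and enablers far above it
(parental tolerance, peer use). The configurational side of the same run:

```python
from likertqca.qca import solution_matrix_text
print(solution_matrix_text(report.nonuse_analysis.intermediate))
```

```
~USE (intermediate)
Factor|Recipe       1       2       3       4       5       6       7       8
GENDER             •       •       •
AGE                ⊗                       ⊗       ⊗
DSCHOOL                                                    •
MONITOR                    •               •                       •
RELIGION                           •               •               •
P_TOLER            ⊗       ⊗       ⊗       ⊗       ⊗       ⊗       ⊗       ⊗
PEER_USE                                                                   ⊗
cons           0.915   0.915   0.921   0.902   0.905   0.897   0.906   0.934
cov            0.287   0.227   0.208   0.325   0.304   0.421   0.266   0.448
solution cons = 0.909   solution cov = 0.673
```

A full circle (•) marks a condition that must be present in a recipe, a
circled x (⊗) one that must be absent, blank means the condition is free.
Here the absence of parental tolerance anchors every non-use recipe —
exactly the configurational asymmetry this kind of analysis is designed to
expose.

The same pipeline runs from the shell:

```
likertqca generate --config study.yaml --seed 7 --out data.csv
likertqca analyze  --config study.yaml --data data.csv --out results/
likertqca report   --results results/
```

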