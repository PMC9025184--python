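# Methods

This note documents the models, conventions and design choices behind
`likertqca`, in the order the pipeline runs them.

## Synthetic survey generator

The generator exists because microdata from school surveys on substance
use are almost never deposited; it emulates the declared *structure* of
such a survey — item inventory, Likert ranges, marginal response
frequencies, scale reliabilities, sample composition and an
effect-structured ordinal outcome — so that every downstream stage has a
realistic, fully controlled input.

**Latent model.** Each multi-item construct follows a single-factor model:
one standard-normal latent draw per respondent, items formed as
`sqrt(r)·latent + sqrt(1−r)·noise`, so any two items correlate `r` on the
latent scale. A single factor with independent item noise is the simplest
structure compatible with reporting only a per-construct Cronbach's alpha;
no secondary factor structure is modelled. Items are discretized at
normal-quantile thresholds matching supplied marginal category
frequencies (a Gaussian-copula construction); without marginals the cuts
are equally spaced on the latent scale over [−1.5, 1.5], a symmetric
default that avoids floor/ceiling pile-ups.

**Defaults as study conditions.** The bundled reference configuration
(`reference_generator_config`) encodes the survey design this package
models: n = 1935 respondents; 53.7% female; ages 15/16/17 with
probabilities (0.543, 0.288, 0.169); the five constructs with their
canonical item counts and the reference marginal frequencies; and latent
inter-item correlations (0.30, 0.32, 0.63, 0.68, 0.72 for DSCHOOL,
MONITOR, RELIGION, P_TOLER, PEER_USE) obtained by inverting the reference
alphas through the Spearman–Brown relation and inflating ≈15% for the
attenuation that 4–5-category discretization induces. Per-cell
missingness defaults to 0.25%, completely at random; across the 44
analysed variables this removes roughly 10% of respondents under listwise
deletion, matching the reference sample's attrition. MCAR is assumed
because only the post-deletion sample size of the reference study is
known, not its missingness mechanism.

**Outcome.** The 7-category outcome is drawn from a proportional-odds
model whose linear predictor combines the gender membership (0/1), the age
membership (0/0.5/1) and z-scored construct sums, with default
coefficients equal to the reference log odds-ratios (−0.960, 0.155,
−0.281, −0.533, −0.742, 3.738, 1.723). Those reference effects were
estimated on membership-scaled predictors, so applying them to
standardized scores reproduces the sign structure and effect ordering, not
the exact marginal effect sizes. Default cutpoints sit at the logits of
the reference cumulative outcome frequencies, so a zero-effect
configuration reproduces the reference outcome marginals (72.5% "never",
…) exactly in expectation.

**Recipe planting.** `plant_recipe` overwrites the outcome for a seeded
fraction of respondents matching a condition-state conjunction, where
"present"/"absent" means sitting strictly above/below the sample median of
the construct sum (female/male for gender, 17/15 for age); respondents
exactly at the median are maximally ambiguous and match neither state.
This gives recovery tests a ground-truth sufficiency structure with
controllable consistency.

**What the generator does not emulate:** inter-construct correlations
(conditions are independent latents; real risk factors cluster),
response styles, informative missingness, and the joint
outcome-by-condition distribution of any real sample. Passing recovery
tests therefore show the *pipeline* is correct under its assumed data
model, not that any substantive result generalizes to real surveys.

## Scales

Cronbach's alpha uses sample (n−1) variances and complete cases per
construct; alpha is computed after generation but the retained analysis
sample is fixed once, globally: a respondent missing *any* analysed item,
gender, age or the outcome is dropped before scoring, and every later
stage (calibration, screening, regression, fsQCA) works on that same
retained set. Construct scores are plain item sums on the raw Likert
codes; no reverse-coded items are assumed because the item inventories are
uniformly directional per construct.

## Calibration

Anchors are the empirical 10th/50th/90th percentiles of the retained
sample, estimated by linear interpolation between order statistics (the
default estimator in the major statistics environments — stated explicitly
because anchors can shift by a raw point across estimator conventions).
Published anchors can be injected verbatim as JSON, bypassing estimation.

The piecewise map is implemented exactly as written: membership 0 *at*
q10, 0.5 *at* q50, 1 *at* q90, right-closed branch boundaries. It requires
q10 < q50 < q90; collapsed anchors (a construct whose 10th percentile and
median coincide, e.g. a heavily floor-concentrated tolerance scale) raise
a degenerate-calibration error naming the construct rather than silently
producing a discontinuous membership with no crossover.

Cases whose condition membership is exactly 0.5 are maximally ambiguous
and belong to no truth-table corner. The pipeline can nudge such
memberships up by a configurable `crossover_epsilon` (0.001 when enabled;
0 = off, the default) — conditions only, never the outcome — and records
the number of adjusted entries. The outcome map {1→0, 2→0.2, 3→0.8,
4→0.9, ≥5→1} is a configured constant: it treats "1–2 times" as mostly
outside the user set and anything from "3–5 times" up as essentially
inside it.

## Contrarian screen

Conditions are screened on their calibrated memberships, binned at the
20/40/60/80 percentiles; the outcome enters as its raw 1–7 code, itself
quintile-binned by default (configurable, since binning the outcome is a
convention rather than a necessity). Tied distributions may collapse bin
edges; collapsed bins are renumbered and logged. Phi is defined as
√(χ²/n) for tables of any size — which can exceed 1 beyond 2×2 — with
Cramér's V reported alongside; tau-b is computed on the same quantities.
Phi² < 0.5 (strict) flags a condition as justifying configurational
analysis.

## Ordered logistic regression

The cumulative-logit likelihood is maximized via
`statsmodels.miscmodels.ordinal_model.OrderedModel` (BFGS), behind the
package's own fitting surface; predictors are the calibrated memberships,
not raw sums. The null model is cutpoints-only, whose MLE is the set of
empirical cumulative logits — this fixes the conventions for the LR test
and McFadden's pseudo-R² (1 − ℓ/ℓ₀). Empty outcome categories are
collapsed with a logged warning (the likelihood is invariant to them).
Confidence intervals use the 1.96 normal multiplier on the log-OR scale.
Non-convergence raises an error carrying the optimizer state; extreme
coefficients or standard errors (complete separation of an almost-crisp
predictor) flag the fit as unstable rather than failing it. No
proportional-odds (Brant) test, interactions or alternative links are
provided.

## fsQCA engine

**Truth table.** All 2^k corners are enumerated (k ≤ 16; the study design
has k = 7, 128 rows). A case's best-fit corner dichotomizes each
membership at 0.5; corner membership vectors for row consistency use the
fuzzy min over affirmed/negated conditions. Rows with fewer best-fit
cases than the frequency cutoff are remainders; observed rows at or above
the consistency cutoff are positive; observed rows below it — including
outright contradictions — are negative, never don't-cares. Defaults:
frequency cutoff 1 case, consistency cutoff 0.8 (the stricter of the two
conventional sufficiency bars), both configurable and echoed in reports.

**Minimization.** Quine–McCluskey with exact cover selection: iterated
pairwise merging yields all prime implicants of positives ∪ don't-cares;
essential primes are taken first (they belong to every cover); the
residual chart is solved by Petrick-style branch and bound. Cover cost is
lexicographic: fewest recipes, then fewest total literals, then a
deterministic ordering (affirmed < negated < free, position by position in
the declared condition order), so output never depends on iteration order.
Optimality over prime implicants only is safe: any valid cube grows to a
prime without increasing either cost term.

**Intermediate solution.** For each parsimonious recipe `p` and each
complex recipe `c` it subsumes, `p` is re-specialized with the literals of
`c` whose state agrees with the directional expectation for the analyzed
outcome; expectation-contradicting literals stay dropped (easy
counterfactuals). Candidates are pooled, duplicates and specializations
of more general candidates removed. For the negated outcome every
expectation direction is reversed. This literal-retention shortcut is
cross-checked in the tests against an independent re-derivation: for each
recipe pair, re-minimizing from scratch with only the remainders reachable
from the complex recipe by moving conditions into their expected
contributing state (all other positives as don't-cares). Note that a
*global* easy-counterfactual minimization — pooling all remainders
reachable from any positive row — is genuinely more permissive than the
pairwise standard procedure; the pairwise semantics is the one
implemented, matching established fsQCA practice.

**Scoring.** Consistency and coverage are the direct ratio definitions;
the solution-level membership is the pointwise max over recipes, so
solution coverage dominates every recipe coverage. Core conditions are
those appearing in the parsimonious solution, peripheral ones appear only
in the intermediate solution. Sufficiency-only: necessity analysis and
PRI consistency are deliberately not computed.

## Pipeline and reporting

Stages run in a fixed order with stage-labelled failure diagnostics, and a
run is byte-reproducible given its seed. Text tables print three decimals;
JSON keeps full precision. The CLI (`generate` / `analyze` / `report`) is
a thin shell over the library; all study-structural settings live in the
YAML/JSON config.

## Problem sizes used in the tests

The suite exercises the generator at n = 300–2000 (n = 100,000 once, for
the outcome-marginal check), ordered-logit recovery at n = 5000 with 100
replicates, minimization against exhaustive search on ≤4 conditions, and
the intermediate-solution cross-check on the full enumeration of
3-condition truth tables. These sizes give stable sampling behaviour for
every assertion while keeping the default test run short.

## Known limitations

- Conditions are generated independently; correlated risk factors would
  stress the truth table differently (more empty rows, more remainders).
- Phi > 1 is possible for large tables by construction of √(χ²/n);
  interpret alongside Cramér's V.
- The calibration is piecewise-linear, not the logistic "direct method";
  memberships between anchors are not invariant to nonlinear monotone
  rescaling of the raw scores (only the anchors themselves are
  rank-based). Affine rescalings are neutral.
- With near-crisp conditions the ordered logit can approach separation;
  the fit is flagged, not repaired.
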