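"""Fuzzy-set qualitative comparative analysis (fsQCA).

Given calibrated memberships for k conditions and an outcome set, the
engine:

1. scores all 2^k corner configurations of the condition space (the truth
   table), assigning each case to the corner where its membership exceeds
   0.5 and each row a sufficiency consistency
   Cons(Z -> Y) = sum_j min(mZ_j, mY_j) / sum_j mZ_j;
2. minimizes the positive rows with the Quine-McCluskey algorithm —
   iterated pairwise merging to prime implicants, essential-prime
   extraction, then an exact (Petrick-style) minimal-cover search — to the
   complex solution (no remainders) and the parsimonious solution (all
   remainder rows usable as don't-cares, contradictions never);
3. derives the intermediate solution from directional expectations: a
   parsimonious recipe is re-specialized with those literals of its complex
   counterparts whose state agrees with the expected direction of
   contribution (dropping them would need a difficult counterfactual),
   while expectation-contradicting literals stay dropped (easy
   counterfactuals);
4. scores every recipe and solution with consistency and coverage
   Cov(Z -> Y) = sum_j min(mZ_j, mY_j) / sum_j mY_j, the solution-level
   membership being the fuzzy union (pointwise max) over its recipes.

Recipes are conjunctions written with "*" for the fuzzy product (min) and
"~" for negation (1 - m).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRESENT = 1
ABSENT = 0
FREE = 2

#: Sort weight per state used for the deterministic lexicographic tie-break:
#: an affirmed condition sorts before a negated one, which sorts before a
#: free one, position by position in the declared condition order.
_STATE_ORDER = {PRESENT: 0, ABSENT: 1, FREE: 2}

DEFAULT_FREQUENCY_CUTOFF = 1
DEFAULT_CONSISTENCY_CUTOFF = 0.8


class QCAError(ValueError):
    """Raised for undefined set measures or invalid minimization inputs."""


# ---------------------------------------------------------------------------
# Implicants

@dataclass(frozen=True)
class Implicant:
    """A conjunction of condition states: per condition present (1), absent
    (0) or free (2).  The all-free implicant is the tautology."""

    conditions: tuple[str, ...]
    states: tuple[int, ...]

    def __post_init__(self):
        if len(self.conditions) != len(self.states):
            raise QCAError("states and conditions must align")
        if any(s not in (PRESENT, ABSENT, FREE) for s in self.states):
            raise QCAError(f"invalid state in {self.states}")

    @property
    def label(self) -> str:
        parts = []
        for cond, s in zip(self.conditions, self.states):
            if s == PRESENT:
                parts.append(cond)
            elif s == ABSENT:
                parts.append(f"~{cond}")
        return "*".join(parts) if parts else "1"

    @classmethod
    def from_label(cls, label: str, conditions: Sequence[str]) -> "Implicant":
        states = [FREE] * len(conditions)
        index = {c: i for i, c in enumerate(conditions)}
        label = label.strip()
        if label not in ("", "1"):
            for token in label.split("*"):
                token = token.strip()
                negated = token.startswith("~")
                name = token[1:].strip() if negated else token
                if name not in index:
                    raise QCAError(f"unknown condition {name!r} in label {label!r}")
                states[index[name]] = ABSENT if negated else PRESENT
        return cls(tuple(conditions), tuple(states))

    @property
    def n_literals(self) -> int:
        return sum(1 for s in self.states if s != FREE)

    @property
    def is_tautology(self) -> bool:
        return self.n_literals == 0

    def sort_key(self) -> tuple[int, ...]:
        return tuple(_STATE_ORDER[s] for s in self.states)

    def covers(self, config: Sequence[int]) -> bool:
        """Whether a fully specified configuration lies inside this cube."""
        return all(s == FREE or s == c for s, c in zip(self.states, config))

    def subsumes(self, other: "Implicant") -> bool:
        """True if ``other`` is a specialization of self (every literal of
        self appears, with the same state, in ``other``)."""
        return all(
            s == FREE or s == o for s, o in zip(self.states, other.states)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def recipe_membership(
    implicant: Implicant, memberships: pd.DataFrame | Mapping[str, np.ndarray]
) -> np.ndarray:
    """Fuzzy membership of every case in the recipe: min over its literals
    of m (affirmed) or 1 - m (negated); the tautology scores 1 everywhere."""
    cols = []
    for cond, s in zip(implicant.conditions, implicant.states):
        if s == FREE:
            continue
        m = np.asarray(memberships[cond], dtype=float)
        cols.append(m if s == PRESENT else 1.0 - m)
    if not cols:
        some = memberships[implicant.conditions[0]]
        return np.ones(len(np.asarray(some)), dtype=float)
    return np.minimum.reduce(cols)


# ---------------------------------------------------------------------------
# Consistency and coverage (sufficiency calibration of a recipe)

def consistency(m_recipe, m_outcome) -> float:
    """sum min(mZ, mY) / sum mZ — degree to which the recipe is a fuzzy
    subset of the outcome."""
    mz = np.asarray(m_recipe, dtype=float)
    my = np.asarray(m_outcome, dtype=float)
    if mz.shape != my.shape:
        raise QCAError("membership vectors must have equal length")
    denom = mz.sum()
    if denom == 0:
        raise QCAError("consistency undefined: recipe membership sums to zero")
    return float(np.minimum(mz, my).sum() / denom)


def coverage(m_recipe, m_outcome) -> float:
    """sum min(mZ, mY) / sum mY — share of the outcome the recipe accounts
    for."""
    mz = np.asarray(m_recipe, dtype=float)
    my = np.asarray(m_outcome, dtype=float)
    if mz.shape != my.shape:
        raise QCAError("membership vectors must have equal length")
    denom = my.sum()
    if denom == 0:
        raise QCAError("coverage undefined: outcome membership sums to zero")
    return float(np.minimum(mz, my).sum() / denom)


# ---------------------------------------------------------------------------
# Truth table

@dataclass
class TruthTableRow:
    configuration: tuple[int, ...]
    n_best_fit: int
    row_consistency: float
    status: str  # "positive" | "negative" | "remainder"


@dataclass
class TruthTable:
    conditions: tuple[str, ...]
    rows: list[TruthTableRow]
    n_cases: int
    n_ambiguous: int  # cases with some membership exactly 0.5, assigned nowhere
    frequency_cutoff: int
    consistency_cutoff: float

    def configurations(self, status: str) -> list[tuple[int, ...]]:
        return [r.configuration for r in self.rows if r.status == status]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                **{
                    cond: [r.configuration[i] for r in self.rows]
                    for i, cond in enumerate(self.conditions)
                },
                "n": [r.n_best_fit for r in self.rows],
                "consistency": [r.row_consistency for r in self.rows],
                "status": [r.status for r in self.rows],
            }
        )


def build_truth_table(
    memberships: pd.DataFrame,
    outcome,
    frequency_cutoff: int = DEFAULT_FREQUENCY_CUTOFF,
    consistency_cutoff: float = DEFAULT_CONSISTENCY_CUTOFF,
) -> TruthTable:
    """Score all 2^k corners of the condition space.

    A case belongs to the corner where each membership is dichotomized at
    0.5; cases with any membership exactly 0.5 are ambiguous, counted in
    ``n_ambiguous`` and assigned to no corner (the calibration module's
    crossover-epsilon policy exists to avoid this).  Row status: remainder
    when fewer than ``frequency_cutoff`` best-fit cases, positive when row
    consistency reaches ``consistency_cutoff``, negative otherwise (observed
    but inconsistent rows are contradictions, treated as negative).
    """
    conds = tuple(memberships.columns)
    k = len(conds)
    if not 1 <= k <= 16:
        raise QCAError("truth table needs between 1 and 16 conditions")
    if frequency_cutoff < 1:
        raise QCAError("frequency_cutoff must be >= 1")
    M = memberships.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != M.shape[0]:
        raise QCAError("outcome vector must align with memberships")

    ambiguous = np.any(M == 0.5, axis=1)
    n_ambiguous = int(ambiguous.sum())
    if n_ambiguous:
        logger.warning(
            "%d case(s) with a membership exactly at the 0.5 crossover are "
            "assigned to no truth-table corner", n_ambiguous,
        )
    corner_idx = (M > 0.5) @ (1 << np.arange(k - 1, -1, -1))
    counts = np.bincount(corner_idx[~ambiguous], minlength=2 ** k)

    rows: list[TruthTableRow] = []
    for code in range(2 ** k):
        config = tuple((code >> (k - 1 - i)) & 1 for i in range(k))
        corner = np.minimum.reduce(
            [M[:, i] if bit else 1.0 - M[:, i] for i, bit in enumerate(config)]
        )
        denom = corner.sum()
        cons = float(np.minimum(corner, y).sum() / denom) if denom > 0 else float("nan")
        n_best = int(counts[code])
        if n_best < frequency_cutoff:
            status = "remainder"
        elif np.isnan(cons) or cons < consistency_cutoff:
            status = "negative"
        else:
            status = "positive"
        rows.append(TruthTableRow(config, n_best, cons, status))
    return TruthTable(
        conds, rows, int(M.shape[0]), n_ambiguous, frequency_cutoff, consistency_cutoff
    )


# ---------------------------------------------------------------------------
# Quine-McCluskey minimization

def _merge(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...] | None:
    """Merge two cubes differing in exactly one specified position."""
    diff = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            continue
        if x == FREE or y == FREE or diff >= 0:
            return None
        diff = i
    if diff < 0:
        return None
    merged = list(a)
    merged[diff] = FREE
    return tuple(merged)


def prime_implicants(allowed: Iterable[tuple[int, ...]]) -> set[tuple[int, ...]]:
    """All prime implicants of the allowed configuration set, by iterated
    pairwise merging.  Every returned cube lies wholly inside ``allowed``."""
    level = {tuple(c) for c in allowed}
    primes: set[tuple[int, ...]] = set()
    while level:
        merged_from: set[tuple[int, ...]] = set()
        next_level: set[tuple[int, ...]] = set()
        items = sorted(level)
        # Only cubes with identical free positions can merge; bucket them.
        buckets: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
        for cube in items:
            key = tuple(i for i, s in enumerate(cube) if s == FREE)
            buckets.setdefault(key, []).append(cube)
        for group in buckets.values():
            for a, b in itertools.combinations(group, 2):
                m = _merge(a, b)
                if m is not None:
                    merged_from.update((a, b))
                    next_level.add(m)
        primes.update(c for c in items if c not in merged_from)
        level = next_level
    return primes


def _cube_covers(cube: tuple[int, ...], config: tuple[int, ...]) -> bool:
    return all(s == FREE or s == c for s, c in zip(cube, config))


def _cube_key(cube: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(_STATE_ORDER[s] for s in cube)


def _n_literals(cube: tuple[int, ...]) -> int:
    return sum(1 for s in cube if s != FREE)


def _exact_cover(
    primes: list[tuple[int, ...]], minterms: list[tuple[int, ...]]
) -> list[tuple[int, ...]]:
    """Minimal cover of ``minterms`` by ``primes``: fewest cubes, then fewest
    total literals, then lexicographic by condition order.  Essential primes
    enter first; the residual chart is solved by exhaustive branch and
    bound (Petrick-style)."""
    covering: dict[tuple[int, ...], list[tuple[int, ...]]] = {
        m: [p for p in primes if _cube_covers(p, m)] for m in minterms
    }
    for m, cover in covering.items():
        if not cover:
            raise QCAError(f"no prime implicant covers minterm {m}")

    chosen: set[tuple[int, ...]] = set()
    for m, cover in covering.items():
        if len(cover) == 1:
            chosen.add(cover[0])
    uncovered = [
        m for m in minterms if not any(_cube_covers(p, m) for p in chosen)
    ]

    def cost(cubes: Iterable[tuple[int, ...]]) -> tuple[int, int, tuple]:
        cubes = list(cubes)
        return (
            len(cubes),
            sum(_n_literals(c) for c in cubes),
            tuple(sorted(_cube_key(c) for c in cubes)),
        )

    best: list[list[tuple[int, ...]]] = []

    def search(uncov: list[tuple[int, ...]], extra: list[tuple[int, ...]]):
        if not uncov:
            cand = sorted(chosen | set(extra), key=_cube_key)
            if not best or cost(cand) < cost(best[0]):
                best[:] = [cand]
            return
        if best and len(chosen) + len(extra) + 1 > len(best[0]):
            return
        # Branch on the hardest minterm (fewest covering primes).
        target = min(uncov, key=lambda m: (len(covering[m]), m))
        for p in sorted(covering[target], key=_cube_key):
            if p in extra:
                continue
            rest = [m for m in uncov if not _cube_covers(p, m)]
            search(rest, extra + [p])

    search(uncovered, [])
    return best[0]


def quine_mccluskey(
    minterms: Iterable[tuple[int, ...]],
    dont_cares: Iterable[tuple[int, ...]] = (),
    conditions: Sequence[str] | None = None,
) -> tuple[list[Implicant], list[Implicant]]:
    """Minimize a Boolean function given as configuration tuples.

    Returns ``(primes, cover)``: all prime implicants of
    minterms U dont_cares, and the minimal cover of the minterms alone
    (don't-cares may simplify cubes but need not be covered).  The cover
    never includes any configuration outside minterms U dont_cares.
    """
    mts = [tuple(int(b) for b in m) for m in minterms]
    dcs = [tuple(int(b) for b in d) for d in dont_cares]
    overlap = set(mts) & set(dcs)
    if overlap:
        raise QCAError(f"minterms and don't-cares overlap: {sorted(overlap)}")
    if not mts:
        return [], []
    k = len(mts[0])
    conds = tuple(conditions) if conditions else tuple(f"X{i + 1}" for i in range(k))
    if len(conds) != k:
        raise QCAError("condition names must match configuration width")

    primes = sorted(prime_implicants(set(mts) | set(dcs)), key=_cube_key)
    cover = _exact_cover(primes, sorted(set(mts)))
    to_imp = lambda cube: Implicant(conds, cube)
    return [to_imp(p) for p in primes], [to_imp(c) for c in cover]


# ---------------------------------------------------------------------------
# Solutions

@dataclass
class Solution:
    """A set of sufficiency recipes for one outcome, with set-theoretic fit."""

    solution_type: str  # "complex" | "parsimonious" | "intermediate"
    outcome_label: str  # "USE" | "~USE"
    conditions: tuple[str, ...]
    recipes: list[Implicant] = field(default_factory=list)
    recipe_consistency: list[float] = field(default_factory=list)
    recipe_coverage: list[float] = field(default_factory=list)
    solution_consistency: float | None = None
    solution_coverage: float | None = None

    @property
    def is_empty(self) -> bool:
        return not self.recipes

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.recipes]

    def to_dict(self) -> dict:
        return {
            "solution_type": self.solution_type,
            "outcome": self.outcome_label,
            "recipes": [
                {
                    "label": r.label,
                    "states": {
                        c: {PRESENT: "present", ABSENT: "absent", FREE: "free"}[s]
                        for c, s in zip(r.conditions, r.states)
                    },
                    "consistency": self.recipe_consistency[i]
                    if i < len(self.recipe_consistency) else None,
                    "coverage": self.recipe_coverage[i]
                    if i < len(self.recipe_coverage) else None,
                }
                for i, r in enumerate(self.recipes)
            ],
            "solution_consistency": self.solution_consistency,
            "solution_coverage": self.solution_coverage,
        }


def solution_statistics(
    solution: Solution,
    memberships: pd.DataFrame | Mapping[str, np.ndarray],
    outcome,
) -> Solution:
    """Fill per-recipe and solution-level consistency/coverage in place.

    The solution membership is the fuzzy union (pointwise max) of its
    recipes.  An empty solution is flagged and left unscored.
    """
    if solution.is_empty:
        logger.warning("empty %s solution for %s: no statistics",
                       solution.solution_type, solution.outcome_label)
        solution.solution_consistency = None
        solution.solution_coverage = None
        return solution
    y = np.asarray(outcome, dtype=float)
    vectors = [recipe_membership(r, memberships) for r in solution.recipes]
    solution.recipe_consistency = [consistency(v, y) for v in vectors]
    solution.recipe_coverage = [coverage(v, y) for v in vectors]
    union = np.maximum.reduce(vectors)
    solution.solution_consistency = consistency(union, y)
    solution.solution_coverage = coverage(union, y)
    return solution


def complex_solution(table: TruthTable, outcome_label: str = "USE") -> Solution:
    """Quine-McCluskey over the positive rows with no remainders."""
    positives = table.configurations("positive")
    sol = Solution("complex", outcome_label, table.conditions)
    if not positives:
        logger.warning("no positive truth-table rows: empty complex solution")
        return sol
    _, cover = quine_mccluskey(positives, (), table.conditions)
    sol.recipes = cover
    return sol


def parsimonious_solution(table: TruthTable, outcome_label: str = "USE") -> Solution:
    """Quine-McCluskey with every remainder row available as a don't-care.
    Negative (including contradictory) rows are hard constraints and are
    never covered."""
    positives = table.configurations("positive")
    sol = Solution("parsimonious", outcome_label, table.conditions)
    if not positives:
        logger.warning("no positive truth-table rows: empty parsimonious solution")
        return sol
    remainders = table.configurations("remainder")
    _, cover = quine_mccluskey(positives, remainders, table.conditions)
    sol.recipes = cover
    return sol


def _normalize_expectations(
    expectations: Mapping[str, str], conditions: Sequence[str]
) -> dict[str, str]:
    out = {}
    for cond in conditions:
        e = expectations.get(cond, "either")
        if e not in ("present", "absent", "either"):
            raise QCAError(f"{cond}: expectation must be present/absent/either")
        out[cond] = e
    return out


def reverse_expectations(expectations: Mapping[str, str]) -> dict[str, str]:
    """Directional expectations for the negated outcome: contributions flip."""
    flip = {"present": "absent", "absent": "present", "either": "either"}
    return {c: flip[e] for c, e in expectations.items()}


def intermediate_solution(
    cs: Solution,
    ps: Solution,
    expectations: Mapping[str, str],
) -> Solution:
    """Specialize each parsimonious recipe with the expectation-consistent
    literals of the complex recipes it subsumes.

    A literal of the complex recipe absent from the parsimonious one is
    retained when its state agrees with the directional expectation for the
    analyzed outcome (dropping it would rest on a difficult counterfactual);
    a contradicting literal stays dropped (an easy counterfactual).  Each
    intermediate recipe therefore lies between its complex and parsimonious
    ancestors in specificity.  ``expectations`` must already be stated for
    the outcome being analyzed (use :func:`reverse_expectations` for the
    negated outcome) and must cover every condition appearing in the complex
    solution.
    """
    conds = ps.conditions
    exp = _normalize_expectations(expectations, conds)
    for r in cs.recipes:
        for cond, s in zip(r.conditions, r.states):
            if s != FREE and cond not in expectations:
                raise QCAError(
                    f"directional expectation missing for condition {cond!r}"
                )
    sol = Solution("intermediate", ps.outcome_label, conds)
    if ps.is_empty:
        return sol

    candidates: list[Implicant] = []
    for p in ps.recipes:
        subsumed = [c for c in cs.recipes if p.subsumes(c)]
        if not subsumed:
            candidates.append(p)
            continue
        for c in subsumed:
            states = list(p.states)
            for i, cond in enumerate(conds):
                if states[i] != FREE or c.states[i] == FREE:
                    continue
                state = c.states[i]
                if (state == PRESENT and exp[cond] == "present") or (
                    state == ABSENT and exp[cond] == "absent"
                ):
                    states[i] = state
            candidates.append(Implicant(conds, tuple(states)))

    # Dedupe and drop candidates strictly subsumed by a more general one.
    unique = sorted(set(candidates), key=lambda r: r.sort_key())
    kept = [
        r for r in unique
        if not any(o != r and o.subsumes(r) for o in unique)
    ]
    sol.recipes = kept
    return sol


# ---------------------------------------------------------------------------
# Full analysis of one outcome

@dataclass
class OutcomeAnalysis:
    outcome_label: str
    truth_table: TruthTable
    complex: Solution
    parsimonious: Solution
    intermediate: Solution
    core_conditions: list[str] = field(default_factory=list)
    peripheral_conditions: list[str] = field(default_factory=list)


def analyze_outcome(
    memberships: pd.DataFrame,
    outcome_membership,
    outcome_label: str,
    expectations: Mapping[str, str],
    frequency_cutoff: int = DEFAULT_FREQUENCY_CUTOFF,
    consistency_cutoff: float = DEFAULT_CONSISTENCY_CUTOFF,
) -> OutcomeAnalysis:
    """Run the full three-solution analysis for USE or ~USE.

    ``outcome_membership`` must be the membership of the *use* set and
    ``expectations`` the directional expectations for use; for the negated
    outcome the membership is complemented and every expectation reversed.
    Core conditions are those appearing in the parsimonious solution;
    peripheral ones appear only in the intermediate solution.
    """
    if outcome_label not in ("USE", "~USE"):
        raise QCAError("outcome_label must be 'USE' or '~USE'")
    y = np.asarray(outcome_membership, dtype=float)
    exp = dict(expectations)
    if outcome_label == "~USE":
        y = 1.0 - y
        exp = reverse_expectations(exp)

    table = build_truth_table(memberships, y, frequency_cutoff, consistency_cutoff)
    cs = complex_solution(table, outcome_label)
    ps = parsimonious_solution(table, outcome_label)
    inter = intermediate_solution(cs, ps, exp)
    for sol in (cs, ps, inter):
        if not sol.is_empty:
            solution_statistics(sol, memberships, y)

    core: list[str] = []
    peripheral: list[str] = []
    for i, cond in enumerate(table.conditions):
        in_ps = any(r.states[i] != FREE for r in ps.recipes)
        in_is = any(r.states[i] != FREE for r in inter.recipes)
        if in_ps:
            core.append(cond)
        elif in_is:
            peripheral.append(cond)
    return OutcomeAnalysis(outcome_label, table, cs, ps, inter, core, peripheral)


# ---------------------------------------------------------------------------
# Reporting

PRESENCE_MARK = "•"  # bullet: condition present
ABSENCE_MARK = "⊗"   # circled times: condition absent


def solution_matrix_text(solution: Solution, float_fmt: str = "{:.3f}") -> str:
    """Text matrix of a solution: one column per recipe, bullet for an
    affirmed condition, circled-x for a negated one, blank when free."""
    if solution.is_empty:
        return f"{solution.outcome_label} ({solution.solution_type}): empty solution"
    width = max(10, *(len(c) for c in solution.conditions))
    ncol = len(solution.recipes)
    header = f"{solution.outcome_label} ({solution.solution_type})"
    lines = [header, f"{'Factor|Recipe':<{width + 2}}" + "".join(
        f"{i + 1:>8}" for i in range(ncol))]
    for i, cond in enumerate(solution.conditions):
        marks = []
        for r in solution.recipes:
            s = r.states[i]
            marks.append(
                PRESENCE_MARK if s == PRESENT else ABSENCE_MARK if s == ABSENT else ""
            )
        lines.append(f"{cond:<{width + 2}}" + "".join(f"{m:>8}" for m in marks))
    lines.append(f"{'cons':<{width + 2}}" + "".join(
        f"{float_fmt.format(c):>8}" for c in solution.recipe_consistency))
    lines.append(f"{'cov':<{width + 2}}" + "".join(
        f"{float_fmt.format(c):>8}" for c in solution.recipe_coverage))
    if solution.solution_consistency is not None:
        lines.append(
            f"solution cons = {float_fmt.format(solution.solution_consistency)}   "
            f"solution cov = {float_fmt.format(solution.solution_coverage)}"
        )
    return "\n".join(lines)


def analysis_to_json(analyses: Sequence[OutcomeAnalysis],
                     path: str | Path | None = None) -> str:
    payload = {
        a.outcome_label: {
            "complex": a.complex.to_dict(),
            "parsimonious": a.parsimonious.to_dict(),
            "intermediate": a.intermediate.to_dict(),
            "core_conditions": a.core_conditions,
            "peripheral_conditions": a.peripheral_conditions,
            "n_ambiguous_cases": a.truth_table.n_ambiguous,
            "frequency_cutoff": a.truth_table.frequency_cutoff,
            "consistency_cutoff": a.truth_table.consistency_cutoff,
        }
        for a in analyses
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
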