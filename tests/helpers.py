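"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code path with
the package: exhaustive cover enumeration for Boolean minimization,
direct-summation set measures, pair counting for tau-b, and a generic
numerical maximization of the proportional-odds likelihood.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

ABSENT, PRESENT, FREE = 0, 1, 2
_ORDER = {PRESENT: 0, ABSENT: 1, FREE: 2}


def cube_configs(cube):
    """All fully specified configurations inside a cube."""
    axes = [(0, 1) if s == FREE else (s,) for s in cube]
    return list(itertools.product(*axes))


def cube_covers(cube, config):
    return all(s == FREE or s == c for s, c in zip(cube, config))


def cube_key(cube):
    return tuple(_ORDER[s] for s in cube)


def n_literals(cube):
    return sum(1 for s in cube if s != FREE)


def brute_force_min_cover(minterms, dont_cares, k):
    """Exhaustive minimal cover: fewest cubes, then fewest literals, then
    lexicographic.  Valid cubes lie wholly inside minterms U dont_cares;
    only maximal valid cubes need be searched (any cover cube can be grown
    to a maximal one without raising either cost term)."""
    minterms = [tuple(m) for m in minterms]
    allowed = set(minterms) | {tuple(d) for d in dont_cares}

    valid = [
        cube for cube in itertools.product((ABSENT, PRESENT, FREE), repeat=k)
        if all(c in allowed for c in cube_configs(cube))
    ]

    def generalizations(cube):
        for i, s in enumerate(cube):
            if s != FREE:
                yield cube[:i] + (FREE,) + cube[i + 1:]

    valid_set = set(valid)
    maximal = [
        cube for cube in valid
        if not any(g in valid_set for g in generalizations(cube))
    ]

    best = None
    for size in range(1, len(minterms) + 1):
        for combo in itertools.combinations(maximal, size):
            if all(any(cube_covers(c, m) for c in combo) for m in minterms):
                cost = (
                    size,
                    sum(n_literals(c) for c in combo),
                    tuple(sorted(cube_key(c) for c in combo)),
                )
                if best is None or cost < best[0]:
                    best = (cost, sorted(combo, key=cube_key))
        if best is not None:
            return best
    raise AssertionError("no cover found")


def random_truth_table(rng, k, p_minterm=0.35, p_dc=0.25):
    """Random minterm/don't-care partition of the 2^k configurations."""
    minterms, dont_cares = [], []
    for config in itertools.product((0, 1), repeat=k):
        u = rng.random()
        if u < p_minterm:
            minterms.append(config)
        elif u < p_minterm + p_dc:
            dont_cares.append(config)
    return minterms, dont_cares


def direct_consistency(mz, my):
    """Eq-by-eq summation, no vectorized shortcuts."""
    num = sum(min(a, b) for a, b in zip(mz, my))
    return num / sum(mz)


def direct_coverage(mz, my):
    num = sum(min(a, b) for a, b in zip(mz, my))
    return num / sum(my)


def tau_b_pair_counting(x, y):
    """tau-b from exhaustive pair enumeration with tie corrections."""
    n = len(x)
    conc = disc = tie_x = tie_y = tie_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_both += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    n1 = tie_x + tie_both
    n2 = tie_y + tie_both
    return (conc - disc) / np.sqrt((n0 - n1) * (n0 - n2))


def proportional_odds_nll(params, X, y_ranked, n_cat):
    """Negative log-likelihood of the cumulative-logit model with raw
    cutpoint parameterization (penalizes disordered cutpoints)."""
    k = X.shape[1]
    beta = params[:k]
    cuts = params[k:]
    if np.any(np.diff(cuts) <= 0):
        return 1e10
    eta = X @ beta
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    lo = edges[y_ranked] - eta
    hi = edges[y_ranked + 1] - eta
    p = expit(hi) - expit(lo)
    if np.any(p <= 0):
        return 1e10
    return -np.sum(np.log(p))


def maximize_proportional_odds(X, y_ranked, n_cat):
    """Generic numerical MLE of the same likelihood, independent of any
    ordered-regression library.  Returns (loglik, beta, cutpoints)."""
    k = X.shape[1]
    _, counts = np.unique(y_ranked, return_counts=True)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    start = np.concatenate([np.zeros(k), np.log(cum / (1 - cum))])
    res = minimize(
        proportional_odds_nll, start, args=(X, y_ranked, n_cat),
        method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
    )
    res = minimize(
        proportional_odds_nll, res.x, args=(X, y_ranked, n_cat),
        method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14},
    )
    return -res.fun, res.x[:k], res.x[k:]


def simulate_proportional_odds(rng, n, beta, cutpoints):
    """Draw (X, y) from the cumulative-logit model with standard-normal
    predictors; y coded 1..J."""
    k = len(beta)
    X = rng.standard_normal((n, k))
    eta = X @ np.asarray(beta)
    cum = expit(np.asarray(cutpoints)[None, :] - eta[:, None])
    u = rng.random(n)
    y = 1 + np.sum(u[:, None] > cum, axis=1)
    return X, y


def easy_counterfactual_intermediate(pos, rem, expectations, conditions,
                                     cs_cover, ps_cover, qmc):
    """Counterfactual-based re-derivation of the intermediate solution.

    For each parsimonious recipe p and each complex recipe c it subsumes,
    re-minimize from scratch: the minterms are the positive configurations
    inside c; don't-cares are the other positive configurations plus those
    remainders inside p reachable from c only by moving conditions into
    their expected contributing state (easy counterfactuals).  Results are
    pooled and specializations dropped, mirroring the solution-level
    aggregation.  ``qmc`` is the minimizer to use (passed in so the oracle
    itself stays free of package internals beyond the Implicant type).
    """
    out = set()
    for p in ps_cover:
        subsumed = [c for c in cs_cover if p.subsumes(c)]
        if not subsumed:
            out.add(p.states)
            continue
        for c in subsumed:
            mts = [m for m in pos if cube_covers(c.states, m)]
            dc = [m for m in pos if not cube_covers(c.states, m)]
            for r in rem:
                if not cube_covers(p.states, r):
                    continue
                easy = True
                for i, lit in enumerate(c.states):
                    if lit == FREE or r[i] == lit:
                        continue
                    e = expectations[conditions[i]]
                    if e == "either":
                        continue
                    contributing = 1 if e == "present" else 0
                    if r[i] != contributing:
                        easy = False
                        break
                if easy:
                    dc.append(r)
            _, cover = qmc(mts, dc, conditions)
            out.update(x.states for x in cover)
    keep = [
        s for s in out
        if not any(o != s and all(a == FREE or a == b for a, b in zip(o, s))
                   for o in out)
    ]
    return sorted(keep)
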