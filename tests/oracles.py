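"""Independent oracles used by the test suite.

Deliberately dumb implementations that share no code path with the
package: brute-force vertex enumeration for LPs, normal-equations
partial rank correlation, and Pearson-on-Savage-scores for the
top-down coefficient.
"""

import itertools

import numpy as np
from scipy import stats


def lp_max_by_vertex_enumeration(S, lb, ub, c, tol=1e-7):
    """Maximize c.v subject to S v = 0, lb <= v <= ub by enumerating
    basic feasible solutions.  Requires finite bounds.  Returns the
    best objective value, or None if no vertex is feasible."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    free = n - rank
    best = None
    for fixed in itertools.combinations(range(n), free):
        rest = [j for j in range(n) if j not in fixed]
        S_rest = S[:, rest]
        if np.linalg.matrix_rank(S_rest, tol=1e-10) < len(rest):
            continue  # underdetermined; vertex reachable via another subset
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            sol, *_ = np.linalg.lstsq(S_rest, rhs, rcond=None)
            v[rest] = sol
            if np.abs(S @ v).max() > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def prcc_normal_equations(x, y):
    """Textbook PRCC: rank transform, then partial correlation of each
    column with y via the inverse of the rank correlation matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    K, p = x.shape
    R = np.column_stack(
        [stats.rankdata(x[:, j]) for j in range(p)] + [stats.rankdata(y)]
    )
    C = np.corrcoef(R, rowvar=False)
    P = np.linalg.inv(C)
    out = np.empty(p)
    for j in range(p):
        out[j] = -P[j, p] / np.sqrt(P[j, j] * P[p, p])
    return out


def savage_scores_reference(values):
    """Savage scores straight from the definition: sort descending,
    assign harmonic tail sums positionally, average over ties."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    tail = np.array([np.sum(1.0 / np.arange(i, n + 1)) for i in range(1, n + 1)])
    order = np.argsort(-v, kind="stable")
    scores = np.empty(n)
    pos = 0
    while pos < n:
        end = pos
        while end + 1 < n and v[order[end + 1]] == v[order[pos]]:
            end += 1
        scores[order[pos:end + 1]] = tail[pos:end + 1].mean()
        pos = end + 1
    return scores


def top_down_via_pearson(values_a, values_b):
    """Pearson correlation of Savage-score vectors (valid oracle for
    untied rankings)."""
    sa = savage_scores_reference(values_a)
    sb = savage_scores_reference(values_b)
    return float(stats.pearsonr(sa, sb).statistic)


def random_bounded_lp_model(rng, max_reactions=8):
    """A random small, bounded, feasible stoichiometric LP wrapped as a
    MetabolicModel (v = 0 is always feasible: every lb <= 0 <= ub)."""
    from csense.fba_core import MetabolicModel, Metabolite, Reaction

    n_rxn = int(rng.integers(4, max_reactions + 1))
    n_met = int(rng.integers(2, 5))
    met_ids = [f"x{i}" for i in range(n_met)]
    rxns = []
    obj = int(rng.integers(0, n_rxn))
    for j in range(n_rxn):
        stoich = {}
        for i in range(n_met):
            if rng.random() < 0.6:
                coef = float(rng.integers(-2, 3))
                if coef:
                    stoich[met_ids[i]] = coef
        if not stoich:
            stoich[met_ids[int(rng.integers(0, n_met))]] = 1.0
        rxns.append(Reaction(
            id=f"r{j}",
            stoichiometry=stoich,
            lb=float(-rng.uniform(0, 10)) if rng.random() < 0.7 else 0.0,
            ub=float(rng.uniform(0, 10)),
            is_objective=(j == obj),
        ))
    return MetabolicModel(
        id=f"rand{rng.integers(0, 10**6)}",
        metabolites=[Metabolite(m) for m in met_ids],
        reactions=rxns,
    )
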