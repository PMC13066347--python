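"""Savage scores and the top-down concordance coefficient (TDCC).

Savage scores replace ranks with harmonic tail sums, so agreement
among top-ranked (high-abundance) items dominates the coefficient —
appropriate when variability is smallest at the top of the ranking.
Rank 1 is always the LARGEST value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    AlignmentError,
    InvalidParameterError,
    UndefinedConcordanceError,
)


def ranks_from_values(values) -> np.ndarray:
    """Top-down ranks: rank 1 for the largest value, average ranks for ties."""
    v = np.asarray(values, dtype=float)
    return stats.rankdata(-v, method="average")


def savage_scores(n: int, ranks) -> np.ndarray:
    """Savage score per item: untied rank i gets sum_{j=i..n} 1/j; tied
    items share the mean of the scores of the positions they occupy."""
    ranks = np.asarray(ranks, dtype=float)
    if len(ranks) != n:
        raise InvalidParameterError(f"expected {n} ranks, got {len(ranks)}")
    if ranks.min() < 1 - 1e-9 or ranks.max() > n + 1e-9:
        raise InvalidParameterError("ranks must lie in 1..n")
    # positional scores: S[i] = 1/(i+1) + ... + 1/n  (0-based i)
    pos = np.cumsum(1.0 / np.arange(n, 0, -1))[::-1]
    scores = np.empty(n)
    for r in np.unique(ranks):
        members = np.where(ranks == r)[0]
        g = len(members)
        # g tied items with average rank r occupy positions r-(g-1)/2 .. r+(g-1)/2
        first = int(round(r - (g - 1) / 2.0))
        if first < 1 or first + g - 1 > n:
            raise InvalidParameterError(f"rank {r} with tie group {g} is inconsistent")
        scores[members] = pos[first - 1: first - 1 + g].mean()
    return scores


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1)))


@dataclass
class RankingPair:
    """Two rankings of the same item set with Savage-score machinery."""

    item_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray

    @classmethod
    def from_values(cls, item_ids, values_a, values_b) -> "RankingPair":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        ids = list(item_ids)
        if not (len(ids) == len(a) == len(b)):
            raise AlignmentError("item ids and value vectors must align")
        return cls(item_ids=ids, values_a=a, values_b=b)

    @property
    def n(self) -> int:
        return len(self.item_ids)

    @property
    def ranks_a(self) -> np.ndarray:
        return ranks_from_values(self.values_a)

    @property
    def ranks_b(self) -> np.ndarray:
        return ranks_from_values(self.values_b)

    @property
    def savage_a(self) -> np.ndarray:
        return savage_scores(self.n, self.ranks_a)

    @property
    def savage_b(self) -> np.ndarray:
        return savage_scores(self.n, self.ranks_b)


def top_down_correlation(pair: RankingPair) -> float:
    """r_T = (sum_i S_a(i) S_b(i) - n) / (n - H_n); equals 1 iff the
    two (untied) rankings are identical."""
    n = pair.n
    if n < 3:
        raise InvalidParameterError("need at least 3 items")
    sa, sb = pair.savage_a, pair.savage_b
    return float((sa @ sb - n) / (n - _harmonic(n)))


def tdcc(rankings: list) -> float:
    """Multi-ranking top-down concordance:
    C_T = (sum_i T_i^2 - b^2 n) / (b^2 (n - H_n)), T_i the sum over
    rankings of item i's Savage score.  Reduces to 1 for b identical
    untied rankings."""
    b = len(rankings)
    if b < 2:
        raise InvalidParameterError("need at least 2 rankings")
    lengths = {len(r) for r in rankings}
    if len(lengths) != 1:
        raise AlignmentError("rankings cover different item counts")
    n = lengths.pop()
    if n < 3:
        raise InvalidParameterError("need at least 3 items")
    T = np.zeros(n)
    for values in rankings:
        T += savage_scores(n, ranks_from_values(values))
    return float((T @ T - b * b * n) / (b * b * (n - _harmonic(n))))


def concordance_report(
    predicted: dict[str, float],
    observed: dict[str, float],
    permutations: int = 99,
    rng_seed: int = 0,
) -> dict:
    """TDCC of predicted vs observed species scores plus a permutation
    p-value obtained by shuffling the observed vector's assignment to
    species: p = (1 + #{permuted r_T >= observed r_T}) / (permutations + 1).
    """
    if permutations < 19:
        raise InvalidParameterError("need at least 19 permutations")
    items = sorted(observed)
    missing = [i for i in items if i not in predicted]
    if missing:
        raise AlignmentError(f"predicted weights missing for: {missing[:5]}")
    pred = np.array([predicted[i] for i in items], dtype=float)
    obs = np.array([observed[i] for i in items], dtype=float)
    if not np.any(pred > 0):
        raise UndefinedConcordanceError("all predicted weights are zero")

    r_obs = top_down_correlation(RankingPair.from_values(items, pred, obs))
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(obs)
        r_perm = top_down_correlation(RankingPair.from_values(items, pred, perm))
        if r_perm >= r_obs:
            exceed += 1
    return {
        "tdcc": r_obs,
        "n_items": len(items),
        "permutation_p": (1 + exceed) / (permutations + 1),
        "permutations": permutations,
    }


def cohort_concordance_report(
    predicted_per_sample: dict[str, dict[str, float]],
    observed_per_sample: dict[str, dict[str, float]],
    permutations: int = 99,
    rng_seed: int = 0,
) -> dict:
    """Averaging convenience: mean per-sample TDCC across a cohort,
    with a permutation null built by independently shuffling each
    sample's observed vector over species."""
    if permutations < 19:
        raise InvalidParameterError("need at least 19 permutations")
    samples = sorted(observed_per_sample)
    if set(predicted_per_sample) != set(observed_per_sample):
        raise AlignmentError("predicted and observed cover different samples")

    aligned = []
    for s in samples:
        obs = observed_per_sample[s]
        pred = predicted_per_sample[s]
        items = sorted(obs)
        missing = [i for i in items if i not in pred]
        if missing:
            raise AlignmentError(f"sample {s}: predicted missing {missing[:5]}")
        p = np.array([pred[i] for i in items], dtype=float)
        o = np.array([obs[i] for i in items], dtype=float)
        if not np.any(p > 0):
            raise UndefinedConcordanceError(f"sample {s}: all predicted weights are zero")
        aligned.append((items, p, o))

    def mean_tdcc(observed_vectors):
        return float(np.mean([
            top_down_correlation(RankingPair.from_values(items, p, o))
            for (items, p, _), o in zip(aligned, observed_vectors)
        ]))

    r_obs = mean_tdcc([o for _, _, o in aligned])
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    null = []
    for _ in range(permutations):
        r_perm = mean_tdcc([rng.permutation(o) for _, _, o in aligned])
        null.append(r_perm)
        if r_perm >= r_obs:
            exceed += 1
    return {
        "tdcc": r_obs,
        "n_samples": len(samples),
        "permutation_p": (1 + exceed) / (permutations + 1),
        "permutations": permutations,
        "null_95th_percentile": float(np.percentile(null, 95)),
    }
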