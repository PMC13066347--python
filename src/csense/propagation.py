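"""Random-walk-with-restart propagation on the signed directed graph.

The influence operator is out-degree normalized with signs preserved:
each node's outgoing weights are divided by the sum of their absolute
values, so influence is distributed over a node's targets and the
operator is sub-stochastic.  The update is

    x <- (1 - restart) * P^T x + restart * s

optionally followed by clamping negative entries to zero (modelling
full consumption of metabolites / extinction of species), and, in
environment mode, by resetting metabolite nodes to their seed values
(pinned Dirichlet-type boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidSeedError, LookupError_, MappingError
from .sensitivity_graph import METABOLITE, SPECIES, SensitivityGraph

SPECIES_SEED = "species_seed"
ENVIRONMENT = "environment"


@dataclass
class SeedSet:
    values: dict[str, float]
    mode: str  # species_seed | environment

    def __post_init__(self):
        if self.mode not in (SPECIES_SEED, ENVIRONMENT):
            raise InvalidSeedError(f"unknown seed mode {self.mode!r}")
        if not self.values:
            raise InvalidSeedError("seed set is empty")
        neg = {k: v for k, v in self.values.items() if v < 0}
        if neg:
            raise InvalidSeedError(f"negative seed values: {neg}")


@dataclass
class PropagationState:
    weights: dict[str, float]
    iterations: int
    converged: bool
    residual_history: list[float]


def normalize_weights(graph: SensitivityGraph) -> tuple[list[str], np.ndarray]:
    """Node order (sorted) and the row-normalized signed operator P.

    P[i, j] = w(i->j) / sum_k |w(i->k)|; rows without out-edges are zero.
    """
    if not graph.edges:
        raise InvalidParameterError("graph has no edges")
    node_ids = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    P = np.zeros((len(node_ids), len(node_ids)))
    for e in graph.edges:
        P[idx[e.source_id], idx[e.target_id]] += e.weight
    out = np.abs(P).sum(axis=1)
    nz = out > 0
    P[nz] /= out[nz, None]
    return node_ids, P


def propagate(
    graph: SensitivityGraph,
    seeds: SeedSet,
    restart: float = 0.3,
    clamp: bool = True,
    absorbing: bool = False,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> PropagationState:
    """Iterate to the (clamped) fixed point; never raises on
    non-convergence — the state carries a ``converged`` flag.

    ``absorbing=True`` makes clamping permanent: once a node hits zero
    it stays extinct even if positive inflow returns.
    """
    if not (0 < restart <= 1):
        raise InvalidParameterError(f"restart must be in (0, 1], got {restart}")
    expected_kind = METABOLITE if seeds.mode == ENVIRONMENT else SPECIES
    for node in seeds.values:
        kind = graph.nodes.get(node)
        if kind is None:
            raise InvalidSeedError(f"seed node {node!r} not in graph")
        if kind != expected_kind:
            raise InvalidSeedError(
                f"{seeds.mode} mode seeds only {expected_kind} nodes, "
                f"got {node!r} ({kind})"
            )

    node_ids, P = normalize_weights(graph)
    idx = {n: i for i, n in enumerate(node_ids)}
    s = np.zeros(len(node_ids))
    for node, v in seeds.values.items():
        s[idx[node]] = v
    pinned = None
    if seeds.mode == ENVIRONMENT:
        pinned = np.array([graph.nodes[n] == METABOLITE for n in node_ids])

    PT = P.T
    x = s.copy()
    dead = np.zeros(len(node_ids), dtype=bool)
    residuals: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x_new = (1.0 - restart) * (PT @ x) + restart * s
        if clamp:
            if absorbing:
                dead |= x_new < 0
                x_new[dead] = 0.0
            else:
                np.clip(x_new, 0.0, None, out=x_new)
        if pinned is not None:
            x_new[pinned] = s[pinned]
        residual = float(np.abs(x_new - x).sum())
        residuals.append(residual)
        x = x_new
        if residual < tol:
            converged = True
            break
    return PropagationState(
        weights={n: float(x[idx[n]]) for n in node_ids},
        iterations=it,
        converged=converged,
        residual_history=residuals,
    )


def seed_from_abundance(table: pd.DataFrame, sample_id: str,
                        top_n: int = 10) -> SeedSet:
    """Seed the ``top_n`` most abundant species at their counts, the
    rest at zero.  Ties at the cutoff break lexicographically by id.
    ``table`` is samples x species."""
    if top_n < 1:
        raise InvalidParameterError("top_n must be >= 1")
    if sample_id not in table.index:
        raise LookupError_(f"sample {sample_id!r} not in abundance table")
    row = table.loc[sample_id].astype(float)
    ordered = sorted(row.index, key=lambda sp: (-row[sp], sp))
    chosen = ordered[: top_n]
    return SeedSet(values={sp: float(row[sp]) for sp in chosen}, mode=SPECIES_SEED)


def seed_from_environment(
    table: pd.DataFrame,
    sample_id: str,
    mapping: dict[str, str],
    graph_metabolites: set[str] | None = None,
) -> SeedSet:
    """Map feature intensities to metabolite nodes and renormalize the
    mapped values to sum 1 (relative abundances as the pinned
    environment).  ``table`` is samples x features.  Features mapping
    to nodes absent from ``graph_metabolites`` are dropped with a
    warning."""
    import logging

    log = logging.getLogger(__name__)
    if sample_id not in table.index:
        raise LookupError_(f"sample {sample_id!r} not in table")
    row = table.loc[sample_id].astype(float)
    values: dict[str, float] = {}
    for feature, met in mapping.items():
        if feature not in row.index:
            continue
        if graph_metabolites is not None and met not in graph_metabolites:
            log.warning("feature %s maps to %s which is not a graph metabolite; ignored",
                        feature, met)
            continue
        values[met] = values.get(met, 0.0) + float(row[feature])
    total = sum(values.values())
    if not values or total <= 0:
        raise MappingError("no features map onto graph metabolite nodes")
    return SeedSet(values={m: v / total for m, v in values.items()}, mode=ENVIRONMENT)


def write_state(state: PropagationState, graph: SensitivityGraph, path) -> None:
    rows = []
    for node in sorted(state.weights):
        rows.append({
            "node_id": node,
            "kind": graph.nodes.get(node, "unknown"),
            "weight": format(state.weights[node], ".12g"),
            "converged": state.converged,
            "iterations": state.iterations,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_state(path) -> tuple[pd.DataFrame, bool, int]:
    df = pd.read_csv(path, sep="\t")
    converged = bool(df["converged"].iloc[0]) if len(df) else False
    iterations = int(df["iterations"].iloc[0]) if len(df) else 0
    return df, converged, iterations
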