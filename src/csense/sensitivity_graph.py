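"""Signed, weighted, directed bipartite species-metabolite graph.

Edges are significant PRCC coefficients: uptake-mode edges point
metabolite -> species (consumption influences growth), secretion-mode
edges point species -> metabolite (growth influences production).  A
negative weight means growth is suppressed when the metabolite becomes
more available.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InvalidParameterError, InvariantError
from .gsa_prcc import SensitivityResult

SPECIES = "species"
METABOLITE = "metabolite"

EDGE_COLUMNS = [
    "source_id", "target_id", "kind_source", "kind_target",
    "species_id", "metabolite_id", "mode", "prcc", "t_stat",
    "p_value", "p_adj", "n_samples",
]


@dataclass(frozen=True)
class Edge:
    source_id: str
    target_id: str
    weight: float  # signed PRCC
    p_value: float
    mode: str  # uptake | secretion
    t_stat: float = math.nan
    p_adj: float = math.nan
    n_samples: int = 0

    @property
    def species_id(self) -> str:
        return self.target_id if self.mode == "uptake" else self.source_id

    @property
    def metabolite_id(self) -> str:
        return self.source_id if self.mode == "uptake" else self.target_id


@dataclass
class SensitivityGraph:
    nodes: dict[str, str]  # node id -> kind
    edges: list[Edge]
    alpha: float = 0.1

    def validate(self) -> None:
        seen = set()
        for e in self.edges:
            kinds = {self.nodes.get(e.source_id), self.nodes.get(e.target_id)}
            if kinds != {SPECIES, METABOLITE}:
                raise InvariantError(
                    f"edge {e.source_id}->{e.target_id} is not bipartite "
                    f"species/metabolite (kinds {kinds})"
                )
            if e.mode == "uptake" and self.nodes[e.source_id] != METABOLITE:
                raise InvariantError("uptake edges must run metabolite -> species")
            if e.mode == "secretion" and self.nodes[e.source_id] != SPECIES:
                raise InvariantError("secretion edges must run species -> metabolite")
            if abs(e.weight) > 1 + 1e-12:
                raise InvariantError(f"edge weight {e.weight} outside [-1, 1]")
            key = (e.source_id, e.target_id, e.mode)
            if key in seen:
                raise InvariantError(f"duplicate edge {key}")
            seen.add(key)

    def species_nodes(self) -> list[str]:
        return sorted(n for n, k in self.nodes.items() if k == SPECIES)

    def metabolite_nodes(self) -> list[str]:
        return sorted(n for n, k in self.nodes.items() if k == METABOLITE)


def build_graph(results: list[SensitivityResult], alpha: float = 0.1,
                adjust: str = "none") -> SensitivityGraph:
    """Filter PRCC coefficients at ``alpha`` and assemble the graph.

    ``adjust="bh"`` applies Benjamini-Hochberg within each species'
    parameter set (each species' GSA is its own screening experiment)
    and thresholds the adjusted p-values instead of the raw ones.
    """
    if not results:
        raise InvalidParameterError("no sensitivity results given")
    if not (0 < alpha < 1):
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if adjust not in ("none", "bh"):
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")

    nodes: dict[str, str] = {}
    edges: list[Edge] = []
    for res in results:
        nodes[res.species_id] = SPECIES
        for par in res.parameters:
            nodes.setdefault(par.metabolite_id, METABOLITE)
        valid = [j for j in range(len(res.parameters))
                 if np.isfinite(res.p_value[j])]
        if not valid:
            continue
        raw = np.array([res.p_value[j] for j in valid])
        if adjust == "bh":
            p_adj = multipletests(raw, method="fdr_bh")[1]
        else:
            p_adj = np.full(len(valid), np.nan)
        for idx, j in enumerate(valid):
            p_use = p_adj[idx] if adjust == "bh" else raw[idx]
            if not p_use < alpha:
                continue
            par = res.parameters[j]
            if par.mode == "uptake":
                src, dst = par.metabolite_id, res.species_id
            else:
                src, dst = res.species_id, par.metabolite_id
            edges.append(Edge(
                source_id=src,
                target_id=dst,
                weight=float(res.prcc[j]),
                p_value=float(res.p_value[j]),
                mode=par.mode,
                t_stat=float(res.t_stat[j]),
                p_adj=float(p_adj[idx]) if adjust == "bh" else math.nan,
                n_samples=res.n_samples,
            ))
    graph = SensitivityGraph(nodes=nodes, edges=edges, alpha=alpha)
    graph.validate()
    return graph


def _fmt(x: float) -> str:
    return "" if (isinstance(x, float) and math.isnan(x)) else format(x, ".12g")


def write_edges(graph: SensitivityGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EDGE_COLUMNS + ["alpha"])
        for e in graph.edges:
            w.writerow([
                e.source_id, e.target_id,
                graph.nodes[e.source_id], graph.nodes[e.target_id],
                e.species_id, e.metabolite_id, e.mode,
                _fmt(e.weight), _fmt(e.t_stat), _fmt(e.p_value), _fmt(e.p_adj),
                e.n_samples, _fmt(graph.alpha),
            ])


def read_edges(path) -> SensitivityGraph:
    nodes: dict[str, str] = {}
    edges: list[Edge] = []
    alpha = 0.1
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "source_id" not in reader.fieldnames:
            raise FormatError(f"{path}: not an edge TSV (missing header)")
        seen = set()
        for row in reader:
            for kind in (row["kind_source"], row["kind_target"]):
                if kind not in (SPECIES, METABOLITE):
                    raise FormatError(f"{path}: unknown node kind {kind!r}")
            key = (row["source_id"], row["target_id"], row["mode"])
            if key in seen:
                raise FormatError(f"{path}: duplicate edge row {key}")
            seen.add(key)
            nodes[row["source_id"]] = row["kind_source"]
            nodes[row["target_id"]] = row["kind_target"]
            edges.append(Edge(
                source_id=row["source_id"],
                target_id=row["target_id"],
                weight=float(row["prcc"]),
                p_value=float(row["p_value"]),
                mode=row["mode"],
                t_stat=float(row["t_stat"]) if row.get("t_stat") else math.nan,
                p_adj=float(row["p_adj"]) if row.get("p_adj") else math.nan,
                n_samples=int(row["n_samples"]) if row.get("n_samples") else 0,
            ))
            if row.get("alpha"):
                alpha = float(row["alpha"])
    graph = SensitivityGraph(nodes=nodes, edges=edges, alpha=alpha)
    graph.validate()
    return graph


def graph_summary(graph: SensitivityGraph) -> dict:
    weights = np.array([e.weight for e in graph.edges], dtype=float)
    hist, bin_edges = np.histogram(weights, bins=10, range=(-1.0, 1.0))
    species_in_edges = {e.species_id for e in graph.edges}
    mets_in_edges = {e.metabolite_id for e in graph.edges}
    return {
        "n_species": len(graph.species_nodes()),
        "n_metabolites": len(graph.metabolite_nodes()),
        "n_species_connected": len(species_in_edges),
        "n_metabolites_connected": len(mets_in_edges),
        "n_edges": len(graph.edges),
        "n_negative": int((weights < 0).sum()),
        "weight_histogram": {
            "bin_edges": bin_edges.tolist(),
            "counts": hist.tolist(),
        },
    }
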