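"""One-command orchestration of the full analysis.

Stages: GSA over every model -> significance-filtered sensitivity
graph -> per-sample propagation (species-seed or pinned-environment
mode) -> top-down concordance against observed abundances.  Every
stage writes its standalone artifact so reruns and debugging can enter
anywhere; a provenance record captures the config, package version,
seeds and per-stage wall time.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import __version__, concordance, gsa_prcc, propagation, sensitivity_graph
from .errors import FormatError, InvalidParameterError
from .fba_core import read_model

log = logging.getLogger("csense.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    models_dir: str
    abundance: str
    environment: str | None = None
    gsa: dict = dataclasses.field(default_factory=dict)
    propagation: dict = dataclasses.field(default_factory=dict)
    tdcc: dict = dataclasses.field(default_factory=dict)

    _GSA_KEYS = {"n_samples", "alpha", "adjust", "range", "seed"}
    _PROP_KEYS = {"restart", "clamp", "absorbing", "tol", "max_iter", "mode", "top_n"}
    _TDCC_KEYS = {"permutations", "seed"}

    def __post_init__(self):
        for name, given, allowed in (
            ("gsa", self.gsa, self._GSA_KEYS),
            ("propagation", self.propagation, self._PROP_KEYS),
            ("tdcc", self.tdcc, self._TDCC_KEYS),
        ):
            unknown = set(given) - allowed
            if unknown:
                raise FormatError(f"config section {name!r}: unknown keys {sorted(unknown)}")
        alpha = self.gsa.get("alpha", 0.1)
        if not (0 < alpha < 1):
            raise InvalidParameterError(f"gsa.alpha must be in (0, 1), got {alpha}")
        if self.gsa.get("adjust", "none") not in ("none", "bh"):
            raise InvalidParameterError("gsa.adjust must be 'none' or 'bh'")
        restart = self.propagation.get("restart", 0.3)
        if not (0 < restart <= 1):
            raise InvalidParameterError(f"propagation.restart must be in (0, 1], got {restart}")
        mode = self.propagation.get("mode", "environment")
        if mode not in ("species", "environment"):
            raise InvalidParameterError("propagation.mode must be 'species' or 'environment'")
        if mode == "environment" and not self.environment:
            raise InvalidParameterError("environment mode requires an environment table")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(doc) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute all stages; returns the tdcc report. Partial outputs are
    retained on failure for debugging."""
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("csense")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    try:
        # --- GSA ---
        t0 = time.perf_counter()
        model_paths = sorted(glob.glob(os.path.join(config.models_dir, "*.json")))
        if not model_paths:
            raise FormatError(f"[gsa] no model JSON files in {config.models_dir!r}")
        models = [read_model(p) for p in model_paths]
        lo, hi = config.gsa.get("range", [0.0, 10.0])
        results = []
        for i, model in enumerate(models):
            design = gsa_prcc.design_for_model(
                model,
                n_samples=int(config.gsa.get("n_samples", 200)),
                rng_seed=int(config.gsa.get("seed", 0)) + i,
                low=float(lo), high=float(hi),
            )
            results.append(gsa_prcc.run_gsa(model, design))
            log.info("gsa: %s done (%d parameters)", model.id, len(design.parameters))
        gsa_prcc.write_results(results, os.path.join(out_dir, "edges.tsv"))
        timings["gsa"] = time.perf_counter() - t0

        # --- graph ---
        t0 = time.perf_counter()
        graph = sensitivity_graph.build_graph(
            results,
            alpha=float(config.gsa.get("alpha", 0.1)),
            adjust=config.gsa.get("adjust", "none"),
        )
        sensitivity_graph.write_edges(graph, os.path.join(out_dir, "graph.tsv"))
        log.info("graph: %s", sensitivity_graph.graph_summary(graph))
        timings["graph"] = time.perf_counter() - t0

        # --- propagation + tdcc ---
        t0 = time.perf_counter()
        abundance = pd.read_csv(config.abundance, sep="\t", index_col=0)
        env = None
        if config.environment:
            env = pd.read_csv(config.environment, sep="\t", index_col=0)
        prop_cfg = config.propagation
        mode = prop_cfg.get("mode", "environment")
        reports = {}
        for sample in abundance.index:
            if mode == "environment":
                mapping = {m: m for m in env.columns}
                seeds = propagation.seed_from_environment(
                    env, sample, mapping,
                    graph_metabolites=set(graph.metabolite_nodes()),
                )
            else:
                seeds = propagation.seed_from_abundance(
                    abundance, sample, top_n=int(prop_cfg.get("top_n", 10)))
            state = propagation.propagate(
                graph, seeds,
                restart=float(prop_cfg.get("restart", 0.3)),
                clamp=bool(prop_cfg.get("clamp", True)),
                absorbing=bool(prop_cfg.get("absorbing", False)),
                tol=float(prop_cfg.get("tol", 1e-8)),
                max_iter=int(prop_cfg.get("max_iter", 10000)),
            )
            propagation.write_state(state, graph,
                                    os.path.join(out_dir, f"state_{sample}.tsv"))
            species = graph.species_nodes()
            predicted = {sp: state.weights.get(sp, 0.0) for sp in species}
            observed = {sp: float(abundance.loc[sample, sp])
                        for sp in species if sp in abundance.columns}
            reports[str(sample)] = concordance.concordance_report(
                predicted, observed,
                permutations=int(config.tdcc.get("permutations", 99)),
                rng_seed=int(config.tdcc.get("seed", 0)),
            )
            log.info("sample %s: tdcc=%.6f p=%.4f", sample,
                     reports[str(sample)]["tdcc"], reports[str(sample)]["permutation_p"])
        timings["propagation_tdcc"] = time.perf_counter() - t0

        report = {
            "samples": reports,
            "mean_tdcc": sum(r["tdcc"] for r in reports.values()) / len(reports),
        }
        with open(os.path.join(out_dir, "tdcc.json"), "w") as fh:
            json.dump(report, fh, indent=1)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump({
                "csense_version": __version__,
                "config": config.to_dict(),
                "stage_wall_time_s": timings,
            }, fh, indent=1)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
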