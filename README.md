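# csense

Community sensitivity analysis toolkit for microbiome–metabolome data.

`csense` builds a signed, directed, bipartite species–metabolite graph
from constraint-based metabolic models: exchange capacities are sampled
with a Latin hypercube, growth is computed by flux balance analysis
(FBA), and each metabolite's partial rank correlation coefficient
(PRCC) with growth becomes a graph edge if it passes a significance
filter. Abundance seeds are then propagated over the graph
(random-walk-with-restart with negative-weight clamping, optionally
with metabolite nodes pinned as a fixed environment) to predict
steady-state community structure, and predictions are scored against
observed species abundances with the top-down concordance coefficient
(TDCC, Savage scores). A metabolomics preprocessing chain (PQN
normalization, QC-RLSC drift correction, QC coefficient-of-variation
filtering) prepares LC-MS feature tables for use as environment seeds.

Because no suitable public data ships with the package, a synthetic
data module generates every input with known ground truth: toy
metabolic models with designed metabolite→growth dependencies,
communities whose abundances follow a log-linear function of available
metabolite capacities, and LC-MS runs with planted dilution, drift,
batches and pooled-QC injections.

## Command line

All stages are exposed under one entry point; every command that uses
randomness takes an explicit `--seed`.

```bash
# generate a synthetic community (models + abundance + environment + truth)
csense simulate community --out demo --seed 7 --n-species 5 --n-mets 8 --n-samples 4

# sensitivity analysis: LHS + FBA + PRCC over all model JSONs
csense gsa --models demo/models --samples 200 --seed 7 --out edges.tsv

# filter at alpha and assemble the bipartite graph
csense graph --edges edges.tsv --alpha 0.1 --adjust none --out graph.tsv

# propagate a seed vector (seeds.tsv: node_id<TAB>value)
csense propagate --graph graph.tsv --seeds seeds.tsv --mode environment \
    --restart 0.3 --clamp on --out state.tsv

# compare predicted species weights with observed abundances
csense tdcc --pred state.tsv --obs demo/abundance.tsv --sample sample0 \
    --permutations 99 --seed 7 --out tdcc.json

# LC-MS preprocessing: PQN -> QC-RLSC -> CV filter
csense simulate lcms --out lcms --seed 3
csense prep --features lcms/features.tsv --injections lcms/injections.tsv \
    --cv-cutoff 30 --out normalized.tsv --removed removed.tsv

# or run everything from one config
csense run --config config.yaml --out run_dir
```

Example `config.yaml`:

```yaml
models_dir: demo/models
abundance: demo/abundance.tsv
environment: demo/environment.tsv
gsa: {n_samples: 200, alpha: 0.1, adjust: none, seed: 7}
propagation: {mode: environment, restart: 0.3, clamp: true}
tdcc: {permutations: 99, seed: 7}
```

`csense run` writes `edges.tsv`, `graph.tsv`, per-sample `state_*.tsv`,
`tdcc.json`, `run.log` and `provenance.json`; reruns with the same
config are bit-identical apart from timings.

## Conventions worth knowing

- Models use the COBRA sign convention: exchange reactions carry one
  metabolite at coefficient −1; negative flux is uptake.
- Toy-model inhibition is a growth-coupled maintenance cost on an
  obligatory uptake (exchange `lb == ub < 0`), since plain FBA growth
  can never decrease when a bound is merely relaxed.
- PRCC significance defaults to raw two-sided p < 0.1;
  Benjamini–Hochberg adjustment (within each species' parameter set)
  is available via `--adjust bh`.
- Propagation clamping is per-iteration and reversible by default;
  `--absorbing` makes extinction permanent.
- TDCC rank 1 is the most abundant item; ties get averaged Savage
  scores.
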