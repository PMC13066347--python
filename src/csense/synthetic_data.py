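"""Synthetic fixtures with known ground truth.

Three generators:

* :func:`make_toy_model` — small feasible stoichiometric models whose
  optimal growth responds monotonically to designed exchange
  capacities (up for required substrates, down for inhibitors).
* :func:`make_community_scenario` — a multi-species community with a
  known metabolite-dependency edge set, per-sample metabolite
  environments, and abundances generated from a log-linear link so
  propagation-based prediction has recoverable signal.
* :func:`make_lcms_scenario` — LC-MS feature tables with planted
  per-sample dilution, smooth injection-order drift, batch labels and
  interleaved pooled-QC injections.

All randomness flows through one ``numpy.random.default_rng`` per
scenario; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError, InvariantError
from .fba_core import MetabolicModel, Metabolite, Reaction
from .metabolome_prep import FeatureTable

BIG = 1e6
#: biomass precursor demand per unit growth for each required metabolite.
#: Small relative to the energy demand (1.0) so growth stays strictly
#: increasing in every required capacity over the working range while
#: still pinning growth to 0 whenever one required capacity is 0.
PRECURSOR_DEMAND = 0.1
DEFAULT_CAPACITY = 10.0
#: obligatory uptake level of inhibitory metabolites (lb == ub on their
#: exchange): FBA cannot express regulatory inhibition, so inhibition is
#: a growth-coupled maintenance cost paid on forced uptake.
INHIBITOR_LOAD = 2.0


def make_toy_model(
    species_id: str,
    required_mets: list[str],
    inhibitory_mets: list[str] | None = None,
    rng_seed: int = 0,
    capacity: float = DEFAULT_CAPACITY,
) -> MetabolicModel:
    """Build a feasible toy model with designed metabolite->growth links.

    Each required metabolite feeds both an energy pool and a dedicated
    biomass precursor, so optimal growth is 0 whenever any required
    uptake capacity is 0 and strictly increasing in each capacity
    otherwise.  Each inhibitory metabolite is taken up obligatorily
    (exchange lb == ub < 0) and drains the energy pool, so growth is
    strictly decreasing in its uptake level.
    """
    inhibitory_mets = list(inhibitory_mets or [])
    required_mets = list(required_mets)
    overlap = set(required_mets) & set(inhibitory_mets)
    if overlap:
        raise InvalidSpecificationError(
            f"metabolites cannot be both required and inhibitory: {sorted(overlap)}"
        )
    if not required_mets:
        raise InvalidSpecificationError("at least one required metabolite is needed")
    if len(required_mets) > 10 or len(inhibitory_mets) > 10:
        raise InvalidSpecificationError("at most 10 metabolites per list")

    rng = np.random.default_rng(rng_seed)
    mets: list[Metabolite] = [Metabolite("energy", "energy pool", is_external=False)]
    rxns: list[Reaction] = []
    biomass_stoich: dict[str, float] = {"energy": -1.0}

    for m in required_mets:
        mets.append(Metabolite(m, m, is_external=True))
        mets.append(Metabolite(f"{m}_c", f"{m} (internal)", is_external=False))
        rxns.append(Reaction(f"EX_{m}", {m: -1.0}, lb=-capacity, ub=0.0,
                             is_exchange=True, exchange_metabolite=m))
        rxns.append(Reaction(f"T_{m}", {m: -1.0, f"{m}_c": 1.0}, lb=0.0, ub=BIG))
        rxns.append(Reaction(f"C_{m}", {f"{m}_c": -1.0, "energy": 1.0}, lb=0.0, ub=BIG))
        biomass_stoich[f"{m}_c"] = -PRECURSOR_DEMAND

    drain_coefficients: dict[str, float] = {}
    for m in inhibitory_mets:
        k = float(rng.uniform(0.5, 1.0))
        drain_coefficients[m] = k
        mets.append(Metabolite(m, m, is_external=True))
        rxns.append(Reaction(f"EX_{m}", {m: -1.0}, lb=-INHIBITOR_LOAD,
                             ub=-INHIBITOR_LOAD, is_exchange=True,
                             exchange_metabolite=m))
        rxns.append(Reaction(f"D_{m}", {m: -1.0, "energy": -k}, lb=0.0, ub=BIG))

    rxns.append(Reaction("biomass", biomass_stoich, lb=0.0, ub=BIG, is_objective=True))

    n_req = len(required_mets)
    model = MetabolicModel(
        id=species_id,
        metabolites=mets,
        reactions=rxns,
        annotations={
            # with equal capacities c the optimum is c * n_req / (1 + n_req * demand);
            # for a single required substrate: growth = capacity * biomass_yield
            "biomass_yield": 1.0 / (1.0 + n_req * PRECURSOR_DEMAND),
            "precursor_demand": PRECURSOR_DEMAND,
            "required": required_mets,
            "inhibitory": inhibitory_mets,
            "inert": [],
            "drain_coefficients": drain_coefficients,
        },
    )
    model.validate()
    return model


def add_inert_exchange(model: MetabolicModel, met_id: str,
                       capacity: float = DEFAULT_CAPACITY) -> MetabolicModel:
    """Add an exchange + transport + sink for a metabolite that cannot
    influence growth (mutates and returns the model)."""
    if any(m.id == met_id for m in model.metabolites):
        raise InvalidSpecificationError(f"metabolite {met_id!r} already in model {model.id!r}")
    model.metabolites.append(Metabolite(met_id, met_id, is_external=True))
    model.metabolites.append(Metabolite(f"{met_id}_c", f"{met_id} (internal)", is_external=False))
    model.reactions.insert(
        len(model.reactions) - 1,
        Reaction(f"EX_{met_id}", {met_id: -1.0}, lb=-capacity, ub=0.0,
                 is_exchange=True, exchange_metabolite=met_id),
    )
    model.reactions.insert(
        len(model.reactions) - 1,
        Reaction(f"T_{met_id}", {met_id: -1.0, f"{met_id}_c": 1.0}, lb=0.0, ub=BIG),
    )
    model.reactions.insert(
        len(model.reactions) - 1,
        Reaction(f"SINK_{met_id}", {f"{met_id}_c": -1.0}, lb=0.0, ub=BIG),
    )
    model.annotations.setdefault("inert", []).append(met_id)
    model.validate()
    return model


@dataclass
class CommunityScenario:
    """A community with known metabolite-dependency ground truth.

    ``dependency_truth`` holds ``(metabolite_id, species_id, sign,
    mode)`` tuples (sign +1/-1, mode ``"uptake"``) that a correct
    sensitivity analysis should recover as graph edges.
    """

    models: list[MetabolicModel]
    dependency_truth: set[tuple[str, str, int, str]]
    abundance: pd.DataFrame  # samples x species, rows sum to 1
    environment: pd.DataFrame  # samples x metabolites, rows sum to 1
    rng_seed: int

    def validate(self) -> None:
        by_id = {m.id: m for m in self.models}
        for met, sp, sign, mode in self.dependency_truth:
            model = by_id.get(sp)
            if model is None:
                raise InvariantError(f"dependency_truth references unknown species {sp!r}")
            if model.exchange_for(met) is None:
                raise InvariantError(
                    f"dependency_truth metabolite {met!r} is not an exchange "
                    f"metabolite of species {sp!r}"
                )
        rows = self.abundance.to_numpy(dtype=float)
        if (rows < 0).any():
            raise InvariantError("abundance entries must be nonnegative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise InvariantError("abundance rows must sum to 1")


def environment_to_capacities(env_row: pd.Series,
                              capacity_scale: float = DEFAULT_CAPACITY) -> pd.Series:
    """Map environment relative abundances to uptake capacities in
    [0, capacity_scale], scaled so the most abundant metabolite gets
    the full capacity."""
    env = env_row.astype(float)
    peak = env.max()
    if peak <= 0:
        return env * 0.0
    return capacity_scale * env / peak


def abundance_from_environment(
    dependency_truth: set[tuple[str, str, int, str]],
    species_ids: list[str],
    env_row: pd.Series,
    beta: float = 1.0,
    capacity_scale: float = DEFAULT_CAPACITY,
) -> pd.Series:
    """Log-linear abundance link: relative abundance proportional to
    exp(beta * net available capacity), where the net capacity of a
    species is the sum of its required metabolites' capacities minus
    the sum of its inhibitory metabolites' capacities."""
    caps = environment_to_capacities(env_row, capacity_scale)
    scores = pd.Series(0.0, index=species_ids)
    for met, sp, sign, _mode in dependency_truth:
        if met in caps.index:
            scores[sp] += sign * caps[met]
    w = np.exp(beta * (scores - scores.max()))
    return w / w.sum()


def make_community_scenario(
    n_species: int,
    n_mets: int,
    n_samples: int,
    rng_seed: int,
    beta: float = 1.0,
    capacity_scale: float = DEFAULT_CAPACITY,
    p_inhibitory: float = 0.5,
) -> CommunityScenario:
    """Generate models, truth edges, environments and linked abundances."""
    if n_species < 2:
        raise InvalidSpecificationError("need at least 2 species")
    if n_mets < n_species:
        raise InvalidSpecificationError("need n_mets >= n_species")
    rng = np.random.default_rng(rng_seed)
    met_ids = [f"m{i:02d}" for i in range(n_mets)]
    species_ids = [f"sp{i}" for i in range(n_species)]

    models = []
    truth: set[tuple[str, str, int, str]] = set()
    for sp in species_ids:
        n_req = int(rng.integers(1, 3))
        required = [str(m) for m in rng.choice(met_ids, size=n_req, replace=False)]
        rest = [m for m in met_ids if m not in required]
        inhibitory = []
        if rest and rng.random() < p_inhibitory:
            inhibitory = [str(rng.choice(rest))]
            rest = [m for m in rest if m not in inhibitory]
        model = make_toy_model(sp, required, inhibitory,
                               rng_seed=int(rng.integers(0, 2**31)),
                               capacity=capacity_scale)
        if rest:
            add_inert_exchange(model, str(rng.choice(rest)), capacity=capacity_scale)
        models.append(model)
        for m in required:
            truth.add((m, sp, +1, "uptake"))
        for m in inhibitory:
            truth.add((m, sp, -1, "uptake"))

    env = rng.dirichlet(np.ones(n_mets), size=n_samples)
    environment = pd.DataFrame(env, index=[f"sample{j}" for j in range(n_samples)],
                               columns=met_ids)
    abundance = pd.DataFrame(
        {s: environment.apply(
            lambda row: abundance_from_environment(truth, species_ids, row,
                                                   beta, capacity_scale)[s],
            axis=1)
         for s in species_ids},
        index=environment.index,
    )
    scenario = CommunityScenario(models=models, dependency_truth=truth,
                                 abundance=abundance, environment=environment,
                                 rng_seed=rng_seed)
    scenario.validate()
    return scenario


@dataclass
class LcmsScenario:
    """Planted ground truth behind a synthetic LC-MS feature table."""

    true_concentrations: pd.DataFrame  # features x samples
    qc_profile: pd.Series  # pooled profile shared by all QC injections
    dilution: pd.Series  # per sample (QC injections have dilution 1)
    drift: pd.Series  # drift factor per injection (function of order)
    batch: pd.Series  # per injection
    qc_flags: pd.Series  # per injection
    noise_cv: float
    rng_seed: int
    drift_slope: float = field(default=0.0)


def make_lcms_scenario(
    n_features: int,
    n_samples: int,
    n_qc: int,
    noise_cv: float,
    rng_seed: int,
    drift_slope: float = 0.01,
    dilution_sigma: float = 0.3,
    n_batches: int = 1,
) -> tuple[LcmsScenario, FeatureTable]:
    """Simulate an LC-MS run: observed = concentration x dilution x
    drift(order) x multiplicative log-normal noise.

    QC injections share one pooled concentration profile (the mean of
    the sample profiles) at dilution 1, and are interleaved evenly
    across the injection order, batch by batch.
    """
    if n_qc < 3:
        raise InvalidSpecificationError("QC-RLSC needs >= 3 QC injections")
    if noise_cv < 0:
        raise InvalidSpecificationError("noise_cv must be nonnegative")
    rng = np.random.default_rng(rng_seed)

    feature_ids = [f"F{i:04d}" for i in range(n_features)]
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    base = 10.0 ** rng.uniform(3.0, 6.0, size=n_features)
    conc = base[:, None] * rng.lognormal(0.0, 0.5, size=(n_features, n_samples))
    true_conc = pd.DataFrame(conc, index=feature_ids, columns=sample_ids)
    qc_profile = true_conc.mean(axis=1)

    total = n_samples + n_qc
    qc_positions = set(np.round(np.linspace(0, total - 1, n_qc)).astype(int).tolist())
    if len(qc_positions) != n_qc:
        raise InvalidSpecificationError("cannot interleave that many QC injections")

    dilution = pd.Series(rng.lognormal(0.0, dilution_sigma, size=n_samples),
                         index=sample_ids)

    rows, columns = [], []
    batch_edges = np.linspace(0, total, n_batches + 1)
    qc_i = samp_i = 0
    for order in range(total):
        batch = f"B{int(np.searchsorted(batch_edges, order, side='right') - 1)}"
        if order in qc_positions:
            inj = f"QC{qc_i:02d}"
            rows.append((inj, "QC_pool", order, batch, True))
            qc_i += 1
        else:
            inj = sample_ids[samp_i]
            rows.append((inj, sample_ids[samp_i], order, batch, False))
            samp_i += 1
        columns.append(inj)
    inj_df = pd.DataFrame(rows, columns=["injection_id", "sample_id", "order",
                                         "batch", "is_qc"]).set_index("injection_id")

    drift = pd.Series(1.0 + drift_slope * inj_df["order"].to_numpy(dtype=float),
                      index=inj_df.index)
    if (drift <= 0).any():
        raise InvalidSpecificationError("drift must stay positive over the run")

    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=(n_features, total))
    else:
        noise = np.ones((n_features, total))

    observed = np.empty((n_features, total))
    for j, inj in enumerate(columns):
        meta = inj_df.loc[inj]
        if meta["is_qc"]:
            profile, dil = qc_profile.to_numpy(), 1.0
        else:
            profile, dil = true_conc[meta["sample_id"]].to_numpy(), dilution[meta["sample_id"]]
        observed[:, j] = profile * dil * drift[inj] * noise[:, j]

    table = FeatureTable(
        intensities=pd.DataFrame(observed, index=feature_ids, columns=columns),
        injections=inj_df,
    )
    scenario = LcmsScenario(
        true_concentrations=true_conc,
        qc_profile=qc_profile,
        dilution=dilution,
        drift=drift,
        batch=inj_df["batch"].copy(),
        qc_flags=inj_df["is_qc"].copy(),
        noise_cv=noise_cv,
        rng_seed=rng_seed,
        drift_slope=drift_slope,
    )
    return scenario, table
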