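"""Global sensitivity analysis: LHS over exchange capacities + PRCC.

For each sampled capacity vector the model's exchange bounds are
overridden and FBA is solved; the partial rank correlation coefficient
between each capacity and optimal growth quantifies how strongly (and
in which direction) metabolite availability controls growth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidDesignError
from .fba_core import MetabolicModel, solve_fba

log = logging.getLogger(__name__)

DEFAULT_RANGE = (0.0, 10.0)


@dataclass(frozen=True)
class GsaParameter:
    metabolite_id: str
    mode: str  # "uptake" | "secretion"
    low: float = DEFAULT_RANGE[0]
    high: float = DEFAULT_RANGE[1]

    def __post_init__(self):
        if self.mode not in ("uptake", "secretion"):
            raise InvalidDesignError(f"unknown mode {self.mode!r}")
        if not self.low < self.high:
            raise InvalidDesignError(
                f"parameter ({self.metabolite_id}, {self.mode}): need low < high"
            )
        if self.low < 0:
            raise InvalidDesignError("capacities are nonnegative")


@dataclass
class GsaDesign:
    parameters: list[GsaParameter]
    n_samples: int
    rng_seed: int

    def __post_init__(self):
        keys = [(p.metabolite_id, p.mode) for p in self.parameters]
        if len(set(keys)) != len(keys):
            raise InvalidDesignError("duplicate (metabolite, mode) parameter")
        if self.n_samples < len(self.parameters) + 3:
            raise InvalidDesignError(
                f"need n_samples >= p+3 = {len(self.parameters) + 3}, "
                f"got {self.n_samples}"
            )


@dataclass
class SensitivityResult:
    species_id: str
    parameters: list[GsaParameter]
    prcc: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    df: int
    growth_samples: np.ndarray
    n_samples: int = field(default=0)

    def __post_init__(self):
        if not self.n_samples:
            self.n_samples = len(self.growth_samples)


def lhs_sample(design: GsaDesign) -> np.ndarray:
    """K x p Latin-hypercube matrix: one uniform draw per equal-width
    stratum per parameter, stratum order shuffled independently."""
    rng = np.random.default_rng(design.rng_seed)
    K, p = design.n_samples, len(design.parameters)
    X = np.empty((K, p))
    for j, par in enumerate(design.parameters):
        u = (np.arange(K) + rng.uniform(size=K)) / K  # one point per stratum
        X[:, j] = par.low + (par.high - par.low) * rng.permutation(u)
    return X


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def prcc(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial rank correlation of each column of ``x`` with ``y``.

    All columns and ``y`` are rank-transformed (average ranks for
    ties).  For column j, both rank(x_j) and rank(y) are residualized
    by ordinary least squares on the other p-1 rank columns plus an
    intercept; PRCC_j is the Pearson correlation of the residuals.
    t = r * sqrt(df / (1 - r^2)) with df = K - 2 - (p - 1); two-sided
    p-values from the t distribution.

    Constant ``y`` yields all-zero coefficients with p = 1 (declared
    convention).  A rank column collinear with the others is dropped
    with a warning and reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    K, p = x.shape
    if y.shape[0] != K:
        raise InvalidDesignError("x and y have different lengths")
    df = K - 2 - (p - 1)
    if df < 1:
        raise InvalidDesignError(f"df = K-2-(p-1) = {df} < 1")

    if np.ptp(y) == 0:
        return np.zeros(p), np.zeros(p), np.ones(p)

    R = np.column_stack([_rank(x[:, j]) for j in range(p)])
    ry = _rank(y)

    r_out = np.empty(p)
    t_out = np.empty(p)
    p_out = np.empty(p)
    for j in range(p):
        others = np.delete(R, j, axis=1)
        Z = np.column_stack([np.ones(K), others])
        res_x = R[:, j] - Z @ np.linalg.lstsq(Z, R[:, j], rcond=None)[0]
        res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        sx = np.sqrt(res_x @ res_x)
        sy = np.sqrt(res_y @ res_y)
        if sx < 1e-10 * np.sqrt(K):
            log.warning("PRCC column %d is collinear with the others; dropped", j)
            r_out[j] = t_out[j] = p_out[j] = np.nan
            continue
        if sy == 0:
            r_out[j], t_out[j], p_out[j] = 0.0, 0.0, 1.0
            continue
        r = float(np.clip((res_x @ res_y) / (sx * sy), -1.0, 1.0))
        if abs(r) >= 1.0:
            t = np.inf if r > 0 else -np.inf
            pv = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            pv = 2.0 * stats.t.sf(abs(t), df)
        r_out[j], t_out[j], p_out[j] = r, t, pv
    return r_out, t_out, p_out


def exchange_overrides(model: MetabolicModel, parameters: list[GsaParameter],
                       capacities: np.ndarray) -> dict[str, tuple[float, float]]:
    """Translate a capacity vector into exchange-bound overrides.

    Uptake capacity u sets exchange lb = -u.  The upper bound is 0
    unless the same metabolite also has a secretion parameter, or the
    model declares the uptake obligatory (exchange ub < 0), in which
    case ub = -u so the forced flux tracks the capacity.
    """
    secretion_mets = {p.metabolite_id for p in parameters if p.mode == "secretion"}
    overrides: dict[str, tuple[float, float]] = {}
    for par, u in zip(parameters, capacities):
        rxn = model.exchange_for(par.metabolite_id)
        if rxn is None:  # caught earlier in run_gsa; defensive
            raise ConfigurationError(f"no exchange for {par.metabolite_id!r}")
        lb, ub = overrides.get(rxn.id, (rxn.lb, rxn.ub))
        if par.mode == "uptake":
            lb = -float(u)
            if par.metabolite_id not in secretion_mets:
                ub = -float(u) if rxn.ub < 0 else 0.0
        else:
            ub = float(u)
        overrides[rxn.id] = (lb, ub)
    return overrides


def run_gsa(model: MetabolicModel, design: GsaDesign) -> SensitivityResult:
    """LHS-sample exchange capacities, solve FBA per row, compute PRCC.

    Rows where the LP is infeasible contribute growth 0 (the species
    cannot grow under those conditions).
    """
    missing = [p.metabolite_id for p in design.parameters
               if model.exchange_for(p.metabolite_id) is None]
    if missing:
        raise ConfigurationError(
            f"model {model.id!r} has no exchange reaction for: {sorted(set(missing))}"
        )
    X = lhs_sample(design)
    growth = np.empty(design.n_samples)
    for k in range(design.n_samples):
        sol = solve_fba(model, exchange_overrides(model, design.parameters, X[k]))
        growth[k] = sol.growth if sol.status == "optimal" else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r, t, pv = prcc(X, growth)
    return SensitivityResult(
        species_id=model.id,
        parameters=list(design.parameters),
        prcc=r,
        t_stat=t,
        p_value=pv,
        df=design.n_samples - 2 - (len(design.parameters) - 1),
        growth_samples=growth,
    )


RESULT_COLUMNS = ["species_id", "metabolite_id", "mode", "prcc", "t_stat",
                  "p_value", "p_adj", "n_samples"]


def write_results(results: list[SensitivityResult], path) -> None:
    """All coefficients (significant or not) as TSV; p_adj left blank —
    adjustment is applied at graph-building time."""
    import csv

    def fmt(x):
        return "" if (x is None or (isinstance(x, float) and np.isnan(x))) else format(x, ".12g")

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for res in results:
            for j, par in enumerate(res.parameters):
                w.writerow([res.species_id, par.metabolite_id, par.mode,
                            fmt(float(res.prcc[j])), fmt(float(res.t_stat[j])),
                            fmt(float(res.p_value[j])), "", res.n_samples])


def read_results(path) -> list[SensitivityResult]:
    """Rebuild per-species results from a coefficient TSV.

    Growth samples are not serialized; the reconstructed results carry
    everything graph building needs.
    """
    import csv

    from .errors import FormatError

    per_species: dict[str, list[dict]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "species_id" not in reader.fieldnames:
            raise FormatError(f"{path}: not a GSA result TSV")
        for row in reader:
            per_species.setdefault(row["species_id"], []).append(row)
    results = []
    for sp, rows in per_species.items():
        params = [GsaParameter(r["metabolite_id"], r["mode"]) for r in rows]
        n = int(rows[0]["n_samples"]) if rows[0].get("n_samples") else 0
        results.append(SensitivityResult(
            species_id=sp,
            parameters=params,
            prcc=np.array([float(r["prcc"]) if r["prcc"] else np.nan for r in rows]),
            t_stat=np.array([float(r["t_stat"]) if r["t_stat"] else np.nan for r in rows]),
            p_value=np.array([float(r["p_value"]) if r["p_value"] else np.nan for r in rows]),
            df=max(n - 2 - (len(params) - 1), 1),
            growth_samples=np.empty(0),
            n_samples=n,
        ))
    return results


def design_for_model(model: MetabolicModel, n_samples: int, rng_seed: int,
                     low: float = DEFAULT_RANGE[0],
                     high: float = DEFAULT_RANGE[1]) -> GsaDesign:
    """Uptake-mode design over every exchange metabolite of the model."""
    params = [
        GsaParameter(r.exchange_metabolite, "uptake", low, high)
        for r in model.reactions
        if r.is_exchange
    ]
    return GsaDesign(parameters=params, n_samples=n_samples, rng_seed=rng_seed)
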