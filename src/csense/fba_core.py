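"""Metabolic model representation and flux balance analysis.

Models follow the COBRA sign convention: an exchange reaction carries a
single metabolite with stoichiometric coefficient -1, so negative flux
is uptake and positive flux is secretion.  FBA maximizes the flux of
the unique biomass (objective) reaction subject to steady-state mass
balance ``S v = 0`` and box bounds on every flux.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import FormatError, InvariantError

#: growth values below this are reported as exactly 0 to stabilize ranks
GROWTH_ZERO_TOL = 1e-8

_MET_KEYS = {"id", "name", "is_external"}
_RXN_KEYS = {
    "id",
    "stoichiometry",
    "lb",
    "ub",
    "is_objective",
    "is_exchange",
    "exchange_metabolite",
}


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_external: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    is_objective: bool = False
    is_exchange: bool = False
    exchange_metabolite: str | None = None


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites, bounded reactions, one objective.

    ``annotations`` holds generator-side metadata (e.g. the analytic
    biomass yield of toy models); it is not serialized and does not
    participate in equality.
    """

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    annotations: dict = field(default_factory=dict, compare=False, repr=False)

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def objective_reaction(self) -> Reaction:
        return next(r for r in self.reactions if r.is_objective)

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """The exchange reaction whose boundary metabolite is ``metabolite_id``."""
        for r in self.reactions:
            if r.is_exchange and r.exchange_metabolite == metabolite_id:
                return r
        return None

    def validate(self) -> None:
        n_obj = sum(r.is_objective for r in self.reactions)
        if n_obj != 1:
            raise InvariantError(
                f"model {self.id!r}: expected exactly one objective reaction, found {n_obj}"
            )
        met_ids = set(self.metabolite_ids())
        if len(met_ids) != len(self.metabolites):
            raise InvariantError(f"model {self.id!r}: duplicate metabolite ids")
        for r in self.reactions:
            if r.lb > r.ub:
                raise InvariantError(
                    f"model {self.id!r}: reaction {r.id!r} has lb {r.lb} > ub {r.ub}"
                )
            unknown = set(r.stoichiometry) - met_ids
            if unknown:
                raise InvariantError(
                    f"model {self.id!r}: reaction {r.id!r} references unknown "
                    f"metabolites {sorted(unknown)}"
                )
            if r.is_exchange:
                if len(r.stoichiometry) != 1:
                    raise InvariantError(
                        f"model {self.id!r}: exchange reaction {r.id!r} must touch "
                        f"exactly one metabolite, touches {len(r.stoichiometry)}"
                    )
                (met, coef), = r.stoichiometry.items()
                if coef != -1:
                    raise InvariantError(
                        f"model {self.id!r}: exchange reaction {r.id!r} must have "
                        f"coefficient -1, has {coef}"
                    )
                if r.exchange_metabolite != met:
                    raise InvariantError(
                        f"model {self.id!r}: exchange reaction {r.id!r} declares "
                        f"metabolite {r.exchange_metabolite!r} but touches {met!r}"
                    )

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with one row per metabolite, one column per reaction."""
        idx = {m: i for i, m in enumerate(self.metabolite_ids())}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[idx[met], j] = coef
        return S


@dataclass
class FbaSolution:
    status: str  # optimal | infeasible | unbounded
    growth: float
    fluxes: dict[str, float]


def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise FormatError(f"{where}: missing required field {key!r}")
    return obj[key]


def model_from_dict(doc: Mapping) -> MetabolicModel:
    if not isinstance(doc, Mapping):
        raise FormatError("model document must be a JSON object")
    mid = _require(doc, "id", "model")
    mets_raw = _require(doc, "metabolites", f"model {mid!r}")
    rxns_raw = _require(doc, "reactions", f"model {mid!r}")
    mets = []
    for m in mets_raw:
        extra = set(m) - _MET_KEYS
        if extra:
            raise FormatError(f"metabolite entry has unknown fields {sorted(extra)}")
        mets.append(
            Metabolite(
                id=_require(m, "id", "metabolite"),
                name=m.get("name", ""),
                is_external=bool(m.get("is_external", False)),
            )
        )
    rxns = []
    for r in rxns_raw:
        extra = set(r) - _RXN_KEYS
        if extra:
            raise FormatError(f"reaction entry has unknown fields {sorted(extra)}")
        rxns.append(
            Reaction(
                id=_require(r, "id", "reaction"),
                stoichiometry={k: float(v) for k, v in _require(r, "stoichiometry", "reaction").items()},
                lb=float(_require(r, "lb", "reaction")),
                ub=float(_require(r, "ub", "reaction")),
                is_objective=bool(r.get("is_objective", False)),
                is_exchange=bool(r.get("is_exchange", False)),
                exchange_metabolite=r.get("exchange_metabolite"),
            )
        )
    model = MetabolicModel(id=mid, metabolites=mets, reactions=rxns)
    model.validate()
    return model


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "is_external": m.is_external}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lb": r.lb,
                "ub": r.ub,
                "is_objective": r.is_objective,
                "is_exchange": r.is_exchange,
                "exchange_metabolite": r.exchange_metabolite,
            }
            for r in model.reactions
        ],
    }


def read_model(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def write_model(model: MetabolicModel, path) -> None:
    model.validate()
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_fba(
    model: MetabolicModel,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FbaSolution:
    """Maximize biomass flux subject to ``S v = 0`` and flux bounds.

    ``overrides`` maps reaction ids to replacement ``(lb, ub)`` pairs.
    Infeasibility/unboundedness is reported in the returned status and
    never raised.  Growth below :data:`GROWTH_ZERO_TOL` is reported as 0.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - {r.id for r in model.reactions}
    if unknown:
        raise KeyError(f"overrides reference unknown reactions: {sorted(unknown)}")

    S = model.stoichiometric_matrix()
    bounds = []
    c = np.zeros(len(model.reactions))
    for j, r in enumerate(model.reactions):
        lb, ub = overrides.get(r.id, (r.lb, r.ub))
        bounds.append((lb, ub))
        if r.is_objective:
            c[j] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FbaSolution(status=status, growth=math.nan, fluxes={})
    growth = float(-res.fun)
    if abs(growth) < GROWTH_ZERO_TOL:
        growth = 0.0
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FbaSolution(status="optimal", growth=growth, fluxes=fluxes)
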