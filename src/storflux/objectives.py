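"""The seven N-limited objective functions and storage predictions.

Each objective proposes a flux distribution for the nitrogen-limited,
carbon-excess phase; the storage-exchange fluxes of that distribution,
expressed in COD units and normalised by the biomass COD, are the predicted
storage accumulation rates.  The closed set of objectives:

``env_moma``
    Minimise the Euclidean distance to the flux distribution of the
    preceding non-limited growth phase (environmental MOMA).
``min_fluxes``
    Minimise the Manhattan norm of the flux vector.
``min_atp`` / ``max_atp``
    Minimise / maximise the gross ATP production rate.
``min_nadh``
    Minimise the gross NADH production rate (NADH only, not NADPH).
``max_storage``
    Maximise the COD-weighted sum of the storage exchange fluxes.
``max_storage_env_moma``
    Lexicographic combination: first maximise total COD storage, then fix the
    total at (1 - tol) of that optimum and run environmental MOMA within the
    remaining solution space.

The non-limited reference required by the MOMA-based objectives is the
growth-maximal flux distribution, made unique by a secondary L1 flux
minimisation at fixed optimal growth (parsimonious selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import (Environment, FluxVector, LinearConstraint, fba_max_growth,
                  l1_minimize, linear_flux_objective, moma_qp)
from .model import MetabolicModel

__all__ = [
    "OBJECTIVE_NAMES",
    "ObjectiveSpec",
    "StoragePrediction",
    "nonlimited_reference",
    "predict_storage",
    "storage_summary",
    "storage_cod_weights",
]

OBJECTIVE_NAMES = ("env_moma", "min_fluxes", "min_atp", "max_atp",
                   "min_nadh", "max_storage", "max_storage_env_moma")

#: Default PHB:PHV co-polymer split on a COD basis.  The organism the toy
#: study emulates accumulates PHA as a PHB-dominated co-polymer; the exact
#: measured proportion must come from user configuration -- this default is
#: prominent, deliberate, and configurable everywhere it is used.
PHB_PHV_COD_RATIO = 0.85

#: Relative slack on the phase-1 storage total in the lexicographic
#: max-storage + environmental-MOMA combination.  On heavily lumped small
#: networks the storage-maximal solution is an isolated vertex, so a purely
#: infinitesimal slack would pin phase 2 to that vertex; a 2 % near-optimal
#: band corresponds to the degenerate optimal face that redundant
#: genome-scale networks exhibit, and is what allows the MOMA step to select
#: a storage mixture.  Configurable per run (``lexicographic_tol``).
LEXICOGRAPHIC_TOL = 0.0075


@dataclass
class ObjectiveSpec:
    """One of the seven objective functions plus its parameters."""

    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in OBJECTIVE_NAMES:
            raise ValueError(
                f"unknown objective {self.name!r}; expected one of "
                f"{OBJECTIVE_NAMES}")

    @property
    def uses_reference(self) -> bool:
        return self.name in ("env_moma", "max_storage_env_moma")


@dataclass
class StoragePrediction:
    """Per-compound storage fluxes in COD units.

    Fluxes are mg-COD of storage compound per g-COD of biomass per hour.
    ``compound_fluxes`` keys are the storage exchange reaction ids' compounds
    (glycogen, phb, phv, tag); :meth:`merged_fractions` reports the measured
    categories (PHA = PHB + PHV; WE is already folded into TAG).
    """

    objective: str
    substrate: str
    compound_fluxes: dict[str, float]
    total_storage_flux: float
    fluxes: FluxVector | None = None
    status: str = "optimal"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def yield_fractions(self) -> dict[str, float]:
        """Per-compound fraction of total storage COD (sums to 1)."""
        if not self.optimal or self.total_storage_flux <= 0:
            raise ValueError("no storage predicted; fractions undefined")
        return {c: f / self.total_storage_flux
                for c, f in self.compound_fluxes.items()}

    def merged_fractions(self) -> dict[str, float]:
        """Fractions with PHB+PHV merged into PHA."""
        fr = self.yield_fractions
        merged = {"glycogen": fr.get("glycogen", 0.0),
                  "pha": fr.get("phb", 0.0) + fr.get("phv", 0.0),
                  "tag": fr.get("tag", 0.0)}
        total = sum(merged.values())
        return {k: v / total for k, v in merged.items()}


def storage_cod_weights(model: MetabolicModel) -> dict[str, float]:
    """COD weight (mg-O2 per mmol exported) of each storage exchange."""
    weights = {}
    for rid in model.storage_exchange_ids:
        rxn = model.reaction(rid)
        met_e = next(m for m, c in rxn.stoichiometry.items()
                     if c > 0 and model.metabolite(m).is_extracellular)
        weights[rid] = model.metabolite(met_e).cod_per_mmol * 1000.0
    return weights


def _compound_name(model: MetabolicModel, rid: str) -> str:
    rxn = model.reaction(rid)
    met_e = next(m for m, c in rxn.stoichiometry.items() if c > 0)
    return met_e.removesuffix("_e")


def nonlimited_reference(model: MetabolicModel, env_growth: Environment,
                         ) -> FluxVector:
    """Growth-maximal reference flux distribution for the non-limited phase.

    The growth LP optimum is generally degenerate; the reference is made
    unique (and hence reproducible) by minimising the L1 flux norm at the
    fixed optimal growth rate.
    """
    if env_growth.n_limited:
        raise ValueError("reference environment must allow growth "
                         "(nh4_uptake > 0)")
    growth = fba_max_growth(model, env_growth)
    if not growth.optimal:
        raise RuntimeError(f"growth FBA {growth.status} under the reference "
                           "environment")
    mu = growth.objective_value
    pin = LinearConstraint({model.biomass_reaction_id: 1.0}, mu, "eq")
    ref = l1_minimize(model, env_growth, constraints=[pin])
    if not ref.optimal:
        raise RuntimeError("L1 selection of the growth reference failed")
    ref.objective_value = mu
    return ref


def _phb_phv_constraint(model: MetabolicModel, cod: dict[str, float],
                        ratio: float) -> LinearConstraint | None:
    """Fix the PHB share of PHA COD at ``ratio`` (co-polymer composition)."""
    by_compound = {_compound_name(model, rid): rid for rid in cod}
    if "phb" not in by_compound or "phv" not in by_compound:
        return None
    rb, rv = by_compound["phb"], by_compound["phv"]
    # (1-ratio) * cod_b * v_b - ratio * cod_v * v_v = 0
    return LinearConstraint(
        {rb: (1.0 - ratio) * cod[rb], rv: -ratio * cod[rv]}, 0.0, "eq")


def predict_storage(model: MetabolicModel, env_growth: Environment,
                    env_limited: Environment, objective: ObjectiveSpec,
                    ngam: float, substrate: str = "",
                    reference: FluxVector | None = None) -> StoragePrediction:
    """Predict the storage mixture accumulated in the N-limited phase.

    ``ngam`` overrides the N-limited environment's maintenance flux.  The
    PHB:PHV co-polymer COD ratio is enforced as a constraint (parameter
    ``phb_phv_cod_ratio``; set to None to leave the split free).
    """
    if not env_limited.n_limited:
        raise ValueError("storage prediction requires an N-limited "
                         "environment (nh4_uptake == 0)")
    env = env_limited.with_ngam(ngam)
    cod = storage_cod_weights(model)
    params = objective.parameters
    constraints: list[LinearConstraint] = []
    ratio = params.get("phb_phv_cod_ratio", PHB_PHV_COD_RATIO)
    if ratio is not None:
        con = _phb_phv_constraint(model, cod, ratio)
        if con:
            constraints.append(con)

    name = objective.name
    if objective.uses_reference and reference is None:
        reference = nonlimited_reference(model, env_growth)

    if name == "env_moma":
        sol = moma_qp(model, env, reference, constraints=constraints)
    elif name == "min_fluxes":
        sol = l1_minimize(model, env, constraints=constraints,
                          include_exchanges=params.get("include_exchanges",
                                                       True))
    elif name in ("min_atp", "max_atp", "min_nadh"):
        from .fba import production_weights
        met = params.get("currency_metabolite",
                         "atp_c" if "atp" in name else "nadh_c")
        sense = "max" if name == "max_atp" else "min"
        sol = linear_flux_objective(model, env, production_weights(model, met),
                                    sense=sense, constraints=constraints)
    elif name == "max_storage":
        sol = linear_flux_objective(model, env, cod, sense="max",
                                    constraints=constraints)
    elif name == "max_storage_env_moma":
        tol = params.get("lexicographic_tol", LEXICOGRAPHIC_TOL)
        phase1 = linear_flux_objective(model, env, cod, sense="max",
                                       constraints=constraints)
        if not phase1.optimal:
            sol = phase1
        else:
            floor = LinearConstraint(dict(cod),
                                     phase1.objective_value * (1.0 - tol),
                                     "ge")
            sol = moma_qp(model, env, reference,
                          constraints=constraints + [floor])
    else:  # pragma: no cover - guarded by ObjectiveSpec
        raise ValueError(name)

    if not sol.optimal:
        return StoragePrediction(objective=name, substrate=substrate,
                                 compound_fluxes={}, total_storage_flux=0.0,
                                 status=sol.status)

    biomass_cod = model.biomass_cod_per_gdw()  # g-COD per g-DW
    compound_fluxes = {}
    for rid, w in cod.items():
        flux = max(0.0, sol[rid])  # storage exports are non-negative
        compound_fluxes[_compound_name(model, rid)] = flux * w / biomass_cod
    total = sum(compound_fluxes.values())
    return StoragePrediction(objective=name, substrate=substrate,
                             compound_fluxes=compound_fluxes,
                             total_storage_flux=total, fluxes=sol)


def storage_summary(prediction: StoragePrediction) -> dict:
    """One report row: merged glycogen/PHA/TAG fractions plus the total.

    An all-zero prediction yields a row flagged ``empty`` (no fractions).
    """
    row = {"objective": prediction.objective,
           "substrate": prediction.substrate,
           "status": prediction.status,
           "total_storage_flux": prediction.total_storage_flux}
    if not prediction.optimal or prediction.total_storage_flux <= 0:
        row.update({"glycogen": None, "pha": None, "tag": None,
                    "empty": True})
        return row
    row.update(prediction.merged_fractions())
    row["empty"] = False
    return row
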