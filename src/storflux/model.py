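"""Core data structures for constraint-based metabolic models.

The model container mirrors the usual COBRA-style layout: metabolites with
elemental formulas and charges, reactions as signed stoichiometry maps, and a
set of designated reactions (biomass, ATP maintenance, storage exchanges).
Storage polymers are handled as *pseudo-secretory* species: an intracellular
polymer unit is exported through a fictional transport ("storage exchange")
reaction so that its accumulation rate shows up as an exchange flux.

Mass balances (rows of S) are written around intracellular metabolites only;
extracellular species are unbalanced, so the exchange/transport reaction that
moves a species across the boundary is its terminal sink or source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ELEMENTS",
    "ELEMENT_MASS",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BiomassComposition",
    "BalanceReport",
    "cod_weight",
    "check_balance",
    "build_stoich_matrix",
    "build_biomass_reaction",
]

#: Elements tracked in formulas (CHNOPS).
ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: Monoisotopic-ish molar masses, g/mol (standard atomic weights).
ELEMENT_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                "P": 30.974, "S": 32.06}

#: Reaction kinds exempt from elemental/charge balance checking.
#: Exchanges, biomass, maintenance and storage exchanges are pseudo-reactions
#: by construction (they move matter across the system boundary or lump
#: unmodelled chemistry).
EXEMPT_KINDS = frozenset({"exchange", "biomass", "maintenance",
                          "storage_exchange"})

REACTION_KINDS = frozenset({"conversion", "transport", "exchange", "biomass",
                            "maintenance", "storage_exchange"})


def cod_weight(formula: dict[str, float], charge: float = 0.0) -> float:
    """Theoretical oxygen demand of a compound, g-O2 per mol.

    Computed from the degree of reduction relative to the CO2/H2O/NH3
    reference states::

        gamma = 4*C + H - 2*O - 3*N + 5*P + 6*S - charge
        ThOD  = 8 * gamma   [g-O2/mol]

    The P and S terms place phosphate (HPO4^2-) and sulfate at zero, the
    conventional reference states, so phosphorylated metabolites carry the
    same ThOD as their dephosphorylated parents.  Glucose (C6H12O6) gives
    192 g-O2/mol, acetate (C2H3O2-) gives 64.

    Negative values (e.g. for O2 itself) are clamped to zero with a warning;
    callers that need the signed electron-balance value (the COD row of a
    reconciliation balance matrix) should use ``cod_weight_signed``.
    """
    val = cod_weight_signed(formula, charge)
    if val < 0:
        warnings.warn(
            f"negative ThOD ({val:.3g} g-O2/mol) clamped to 0 for formula "
            f"{formula} charge {charge}", stacklevel=2)
        return 0.0
    return val


def cod_weight_signed(formula: dict[str, float], charge: float = 0.0) -> float:
    """Signed ThOD (g-O2/mol); negative for oxidants such as O2 (-32)."""
    for el in formula:
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r} in formula {formula}")
    gamma = (4 * formula.get("C", 0.0) + formula.get("H", 0.0)
             - 2 * formula.get("O", 0.0) - 3 * formula.get("N", 0.0)
             + 5 * formula.get("P", 0.0) + 6 * formula.get("S", 0.0)
             - charge)
    return 8.0 * gamma


def formula_mass(formula: dict[str, float]) -> float:
    """Molar mass of a CHNOPS formula, g/mol."""
    return sum(ELEMENT_MASS[el] * n for el, n in formula.items())


@dataclass
class Metabolite:
    """A chemical species.

    ``formula`` maps element symbol to count.  Counts are integers for real
    compounds; lumped pseudo-species (the biomass unit) may carry fractional
    counts, since their formula is an elemental composition per lumped unit.
    """

    id: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: float = 0.0
    compartment: str = "c"  # "c" intracellular, "e" extracellular

    @property
    def cod_per_mmol(self) -> float:
        """ThOD in g-O2 per mmol (== mg-O2 per mmol numerically equals g/mol /1000)."""
        if self.formula is None:
            raise ValueError(f"metabolite {self.id} has no formula")
        return cod_weight(self.formula, self.charge) / 1000.0

    @property
    def is_extracellular(self) -> bool:
        return self.compartment == "e"


@dataclass
class Reaction:
    """A reaction as a signed stoichiometry map (negative = consumed).

    Bounds are in mmol/(g-DW.h); the biomass reaction's flux is 1/h.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1e4
    genes: tuple[str, ...] = ()
    subsystem: str = ""
    kind: str = "conversion"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower bound {self.lower_bound} exceeds upper "
                f"bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def equation(self, arrow: str | None = None) -> str:
        """Human-readable equation string, e.g. ``g6p <=> f6p``."""
        if arrow is None:
            arrow = "<=>" if self.reversible else "->"
        subs, prods = [], []
        for met, coeff in sorted(self.stoichiometry.items()):
            c = abs(coeff)
            term = met if abs(c - 1.0) < 1e-12 else f"{c:.12g} {met}"
            (subs if coeff < 0 else prods).append(term)
        return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}"


@dataclass
class BalanceReport:
    """Outcome of an elemental/charge balance check for one reaction."""

    reaction_id: str
    imbalances: dict[str, float] = field(default_factory=dict)
    exempt: bool = False
    uncheckable: tuple[str, ...] = ()  # metabolites without formulas

    @property
    def balanced(self) -> bool:
        return not self.imbalances and not self.uncheckable


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str = ""
    maintenance_reaction_id: str = ""
    storage_exchange_ids: tuple[str, ...] = ()
    gam: float = 0.0  # mmol-ATP per g-DW embedded in the biomass reaction
    id: str = "model"

    def __post_init__(self) -> None:
        self._index()
        self.validate_designations()

    def _index(self) -> None:
        self.metabolite_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.reaction_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self.metabolite_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self.reaction_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")

    def validate_designations(self) -> None:
        for rid in ((self.biomass_reaction_id, self.maintenance_reaction_id)
                    + tuple(self.storage_exchange_ids)):
            if rid and rid not in self.reaction_index:
                raise ValueError(f"designated reaction {rid!r} not in model")
        missing = [m for r in self.reactions for m in r.stoichiometry
                   if m not in self.metabolite_index]
        if missing:
            raise ValueError(
                f"reactions reference unknown metabolites: {sorted(set(missing))}")

    # -- convenience accessors -------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index[rid]]

    @property
    def balanced_metabolite_ids(self) -> list[str]:
        """Intracellular species: the rows of S."""
        return [m.id for m in self.metabolites if not m.is_extracellular]

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def exchange_for(self, met_id_e: str) -> Reaction:
        """The exchange reaction touching the given extracellular species."""
        for r in self.reactions:
            if r.kind in ("exchange", "storage_exchange") and met_id_e in r.stoichiometry:
                return r
        raise KeyError(f"no exchange reaction touches {met_id_e!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m, formula=dict(m.formula) if m.formula else None)
                         for m in self.metabolites],
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            maintenance_reaction_id=self.maintenance_reaction_id,
            storage_exchange_ids=tuple(self.storage_exchange_ids),
            gam=self.gam,
            id=self.id,
        )

    def biomass_cod_per_gdw(self) -> float:
        """COD content of biomass, g-O2 per g-DW.

        Derived from the biomass product species of the biomass reaction:
        (ThOD per mmol of biomass unit) x (mmol of unit formed per unit flux).
        """
        rxn = self.biomass_reaction
        prods = [(mid, c) for mid, c in rxn.stoichiometry.items()
                 if c > 0 and self.metabolite(mid).is_extracellular
                 and self.metabolite(mid).formula is not None
                 and self.metabolite(mid).formula.get("C", 0) > 0]
        if not prods:
            raise ValueError("biomass reaction has no carbonaceous product")
        mid, coeff = max(prods, key=lambda t: t[1])
        return coeff * self.metabolite(mid).cod_per_mmol


def build_stoich_matrix(model: MetabolicModel) -> tuple[np.ndarray, list[str]]:
    """Stoichiometric matrix over balanced (intracellular) metabolites.

    Returns ``(S, row_ids)``; columns follow ``model.reactions`` order.
    """
    rows = model.balanced_metabolite_ids
    row_index = {mid: i for i, mid in enumerate(rows)}
    S = np.zeros((len(rows), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            i = row_index.get(mid)
            if i is not None:
                S[i, j] = coeff
    return S, rows


def check_balance(reaction: Reaction, metabolites: dict[str, Metabolite] | MetabolicModel,
                  tol: float = 1e-6) -> BalanceReport:
    """Element and charge balance report for one reaction.

    Exchange/biomass/maintenance/storage-exchange reactions are flagged
    exempt (pseudo-reactions), not failed.  Metabolites lacking a formula
    make the reaction "uncheckable" rather than silently passing.
    """
    if isinstance(metabolites, MetabolicModel):
        lookup = {m.id: m for m in metabolites.metabolites}
    else:
        lookup = metabolites
    if reaction.kind in EXEMPT_KINDS:
        return BalanceReport(reaction.id, exempt=True)
    missing = tuple(mid for mid in reaction.stoichiometry
                    if lookup[mid].formula is None)
    if missing:
        return BalanceReport(reaction.id, uncheckable=missing)
    totals: dict[str, float] = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        met = lookup[mid]
        for el, n in (met.formula or {}).items():
            totals[el] += coeff * n
        charge += coeff * met.charge
    imbal = {el: v for el, v in totals.items() if abs(v) > tol}
    if abs(charge) > tol:
        imbal["charge"] = charge
    return BalanceReport(reaction.id, imbalances=imbal)


@dataclass
class BiomassComposition:
    """Macromolecular biomass composition plus precursor stoichiometries.

    ``fractions``: g of macromolecule per g-DW (must sum to 1 +/- 0.01;
    ash is excluded from the accounting).  ``precursors`` maps each
    macromolecule to {metabolite id: mmol per g of macromolecule}; positive
    entries are consumed, negative entries are by-products (e.g. CoA returned
    when acetyl-CoA carbon is incorporated).
    """

    fractions: dict[str, float]
    precursors: dict[str, dict[str, float]]
    name: str = "biomass"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions.values()):
            raise ValueError("macromolecule fractions must be positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(
                f"macromolecule fractions sum to {total:.4f}, expected 1 +/- 0.01")
        if set(self.precursors) != set(self.fractions):
            raise ValueError("precursor table keys must match fraction keys")

    def demand_per_gdw(self) -> dict[str, float]:
        """Net precursor demand, mmol per g-DW (negative = produced)."""
        demand: dict[str, float] = {}
        for macro, frac in self.fractions.items():
            for mid, per_g in self.precursors[macro].items():
                demand[mid] = demand.get(mid, 0.0) + frac * per_g
        return {k: v for k, v in demand.items() if abs(v) > 1e-12}


def build_biomass_reaction(
    composition: BiomassComposition,
    metabolites: dict[str, Metabolite],
    gam: float,
    biomass_met_id: str = "biomass_e",
    reaction_id: str = "BIOMASS",
    energy_ids: dict[str, str] | None = None,
) -> tuple[Reaction, Metabolite]:
    """Assemble a biomass reaction from a composition table.

    The biomass product's elemental formula is *derived* as the exact element
    difference between consumed and produced precursors (protons added to
    bring the derived charge to zero), which makes the biomass reaction
    elementally consistent by construction and gives the model a well-defined
    biomass COD.  The product coefficient is scaled so that unit flux forms
    exactly 1 g-DW (the unit's molar mass defines the g-DW).

    GAM is added as ``gam`` x (ATP + H2O -> ADP + Pi + H) on top of the
    composition's precursor demand.
    """
    energy = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h": "h_c",
              "h2o": "h2o_c"}
    if energy_ids:
        energy.update(energy_ids)

    demand = composition.demand_per_gdw()
    for mid in demand:
        if mid not in metabolites:
            raise ValueError(f"biomass precursor {mid!r} not in model "
                             f"(unmapped precursors: "
                             f"{sorted(m for m in demand if m not in metabolites)})")

    # Elemental content of the consumed precursors, per g-DW nominal.
    elements: dict[str, float] = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for mid, mmol in demand.items():
        met = metabolites[mid]
        if met.formula is None:
            raise ValueError(f"biomass precursor {mid} lacks a formula")
        for el, n in met.formula.items():
            elements[el] += mmol * n
        charge += mmol * met.charge
    # Neutralise the derived unit by consuming/releasing protons.
    h_for_neutrality = -charge  # mmol H+ consumed per g-DW (may be negative)
    elements["H"] += h_for_neutrality
    elements = {el: v for el, v in elements.items() if abs(v) > 1e-9}

    # Composition tables are never gram-exact once by-products are netted
    # out; rescale the demand so that unit flux forms exactly 1 g-DW (the
    # biomass unit is defined as 1 mmol of mass 1000 mg).
    raw_mass = formula_mass(elements)
    scale = 1000.0 / raw_mass
    demand = {mid: mmol * scale for mid, mmol in demand.items()}
    h_for_neutrality *= scale
    elements = {el: v * scale for el, v in elements.items()}
    coeff = 1.0  # mmol of unit per g-DW

    biomass_met = Metabolite(
        id=biomass_met_id, name=f"biomass unit ({composition.name})",
        formula=elements, charge=0.0, compartment="e")

    stoich: dict[str, float] = {mid: -mmol for mid, mmol in demand.items()}

    def _add(mid: str, val: float) -> None:
        stoich[mid] = stoich.get(mid, 0.0) + val

    _add(energy["atp"], -gam)
    _add(energy["h2o"], -gam)
    _add(energy["adp"], gam)
    _add(energy["pi"], gam)
    _add(energy["h"], gam)
    _add(energy["h"], -h_for_neutrality)
    stoich[biomass_met_id] = coeff
    stoich = {k: v for k, v in stoich.items() if abs(v) > 1e-12}

    rxn = Reaction(id=reaction_id, stoichiometry=stoich, lower_bound=0.0,
                   upper_bound=1e4, kind="biomass",
                   name=f"biomass synthesis ({composition.name})")
    return rxn, biomass_met
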