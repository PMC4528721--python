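"""Reading, writing and editing metabolic models.

Three formats are supported:

* a delimited tabular dialect (one reaction table + one metabolite table,
  TSV/CSV) matching the layout of curated model spreadsheets -- equations use
  arrow syntax (``A + 2 B <=> C``);
* SBML Level 3 with the FBC package (bounds, objective) via python-libsbml;
* a JSON dump used for fixtures and round-trips.

Also here: isoenzyme deduplication (merging reactions with identical net
stoichiometry) and biomass-composition swapping.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import replace
from fractions import Fraction

import pandas as pd

from .model import (BiomassComposition, MetabolicModel, Metabolite, Reaction,
                    build_biomass_reaction)

__all__ = [
    "ModelFormatError",
    "ModelReferenceError",
    "load_model_tables",
    "write_model_tables",
    "parse_equation",
    "deduplicate_reactions",
    "swap_biomass",
    "model_to_json",
    "model_from_json",
    "write_sbml",
    "read_sbml",
]

BIG_BOUND = 1e4


class ModelFormatError(ValueError):
    """A table is missing required columns or has unparseable rows."""


class ModelReferenceError(ValueError):
    """An equation references metabolites absent from the metabolite table."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> dict[str, float] | None:
    """Parse ``C6H12O6``-style formulas; empty/NaN yields None."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return None
    text = str(text).strip()
    if not text or text.lower() in ("na", "none", "-"):
        return None
    out: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ModelFormatError(f"cannot parse formula {text!r}")
        el, num = m.group(1), m.group(2)
        n = float(num) if num else 1.0
        out[el] = out.get(el, 0.0) + n
        pos = m.end()
    if pos != len(text):
        raise ModelFormatError(f"cannot parse formula {text!r}")
    return out


def format_formula(formula: dict[str, float] | None) -> str:
    if not formula:
        return ""
    parts = []
    for el in sorted(formula):
        n = formula[el]
        if abs(n - round(n)) < 1e-9:
            n = int(round(n))
        parts.append(f"{el}{n if n != 1 else ''}")
    return "".join(parts)


_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` into a stoichiometry map and reversibility."""
    text = text.strip()
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelFormatError(f"no reaction arrow in equation {text!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = text.split(arrow, 1)

    def side(chunk: str, sign: float, into: dict[str, float]) -> None:
        chunk = chunk.strip()
        if not chunk:
            return
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(Fraction(parts[0]))
                except ValueError as exc:
                    raise ModelFormatError(
                        f"bad coefficient {parts[0]!r} in {text!r}") from exc
                met = parts[1]
            else:
                raise ModelFormatError(f"cannot parse term {term!r} in "
                                       f"{text!r}")
            into[met] = into.get(met, 0.0) + sign * coeff

    stoich: dict[str, float] = {}
    side(left, -1.0, stoich)
    side(right, +1.0, stoich)
    return {k: v for k, v in stoich.items() if v != 0.0}, reversible


def _require_columns(df: pd.DataFrame, cols: set[str], table: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ModelFormatError(
            f"{table} table is missing required columns: {sorted(missing)}")


def load_model_tables(reaction_table, metabolite_table,
                      sep: str | None = None, model_id: str = "model",
                      ) -> MetabolicModel:
    """Load a model from delimited reaction + metabolite tables.

    Required reaction columns: ``id``, ``equation``; recognised optional
    ones: ``name``, ``directionality`` (``reversible``/``irreversible``),
    ``lower_bound``, ``upper_bound``, ``kind``, ``genes`` (semicolon
    separated), ``subsystem``.  Required metabolite columns: ``id``;
    optional: ``name``, ``formula``, ``charge``, ``compartment``.
    Designations (biomass/maintenance/storage exchanges) come from the
    ``kind`` column.  Unparseable rows are reported with their row numbers.
    """
    kw = {"sep": sep} if sep else {"sep": None, "engine": "python"}
    rxn_df = pd.read_csv(reaction_table, **kw)
    met_df = pd.read_csv(metabolite_table, **kw)
    rxn_df.columns = [c.strip().lower() for c in rxn_df.columns]
    met_df.columns = [c.strip().lower() for c in met_df.columns]
    _require_columns(rxn_df, {"id", "equation"}, "reaction")
    _require_columns(met_df, {"id"}, "metabolite")

    metabolites = []
    for _, row in met_df.iterrows():
        metabolites.append(Metabolite(
            id=str(row["id"]).strip(),
            name=str(row.get("name", "") or ""),
            formula=parse_formula(row.get("formula")),
            charge=float(row.get("charge", 0.0) or 0.0),
            compartment=str(row.get("compartment", "c") or "c").strip(),
        ))
    known = {m.id for m in metabolites}

    reactions, bad_rows, missing_refs = [], [], set()
    biomass_id = maintenance_id = ""
    storage_ids: list[str] = []
    for i, row in rxn_df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            stoich, eq_reversible = parse_equation(str(row["equation"]))
        except ModelFormatError as exc:
            bad_rows.append((rownum, str(exc)))
            continue
        absent = set(stoich) - known
        if absent:
            missing_refs |= absent
            continue
        direction = str(row.get("directionality", "") or "").strip().lower()
        reversible = (direction == "reversible") if direction else eq_reversible
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        lb = float(lb) if lb is not None and not pd.isna(lb) else \
            (-BIG_BOUND if reversible else 0.0)
        ub = float(ub) if ub is not None and not pd.isna(ub) else BIG_BOUND
        if not reversible:
            lb = max(lb, 0.0)
        kind = str(row.get("kind", "conversion") or "conversion").strip()
        genes = str(row.get("genes", "") or "")
        rid = str(row["id"]).strip()
        reactions.append(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            genes=tuple(g.strip() for g in genes.split(";") if g.strip()),
            subsystem=str(row.get("subsystem", "") or ""),
            kind=kind, name=str(row.get("name", "") or "")))
        if kind == "biomass":
            biomass_id = rid
        elif kind == "maintenance":
            maintenance_id = rid
        elif kind == "storage_exchange":
            storage_ids.append(rid)

    if missing_refs:
        raise ModelReferenceError(
            "equations reference metabolites absent from the metabolite "
            f"table: {sorted(missing_refs)}")
    if bad_rows:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in bad_rows)
        raise ModelFormatError(f"unparseable reaction rows: {detail}")

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions,
        biomass_reaction_id=biomass_id, maintenance_reaction_id=maintenance_id,
        storage_exchange_ids=tuple(storage_ids), id=model_id)


def write_model_tables(model: MetabolicModel, reaction_path, metabolite_path,
                       sep: str = "\t") -> None:
    """Write the tabular dialect (round-trips through load_model_tables)."""
    rxn_rows = [{
        "id": r.id,
        "name": r.name,
        "equation": r.equation(),
        "directionality": "reversible" if r.reversible else "irreversible",
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "kind": r.kind,
        "genes": ";".join(r.genes),
        "subsystem": r.subsystem,
    } for r in model.reactions]
    met_rows = [{
        "id": m.id,
        "name": m.name,
        "formula": format_formula(m.formula),
        "charge": m.charge,
        "compartment": m.compartment,
    } for m in model.metabolites]
    pd.DataFrame(rxn_rows).to_csv(reaction_path, sep=sep, index=False)
    pd.DataFrame(met_rows).to_csv(metabolite_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# isoenzyme deduplication
# ---------------------------------------------------------------------------

def _canonical_key(rxn: Reaction) -> tuple:
    """Stoichiometry key invariant to scale and (for reversibles) orientation.

    Coefficients are normalised by the smallest absolute coefficient; the
    orientation making the lexicographically smallest metabolite id positive
    is chosen for reversible reactions.
    """
    items = sorted(rxn.stoichiometry.items())
    scale = min(abs(c) for _, c in items)
    norm = [(m, c / scale) for m, c in items]
    if rxn.reversible and norm and norm[0][1] < 0:
        norm = [(m, -c) for m, c in norm]
    return tuple((m, round(c, 9)) for m, c in norm) + (rxn.reversible,)


def deduplicate_reactions(model: MetabolicModel) -> MetabolicModel:
    """Merge isoenzyme duplicates (identical net stoichiometry).

    Gene lists of merged reactions are unioned; the first reaction's id and
    bounds win (bounds of the packaged models are all unbounded-by-default,
    so the flux space is preserved).  Idempotent.
    """
    keep: dict[tuple, Reaction] = {}
    order: list[tuple] = []
    protected = {model.biomass_reaction_id, model.maintenance_reaction_id,
                 *model.storage_exchange_ids}
    for rxn in model.reactions:
        key = ("__protected__", rxn.id) if rxn.id in protected \
            else _canonical_key(rxn)
        if key in keep:
            prev = keep[key]
            genes = tuple(dict.fromkeys(prev.genes + rxn.genes))
            lb = min(prev.lower_bound, rxn.lower_bound)
            ub = max(prev.upper_bound, rxn.upper_bound)
            keep[key] = replace(prev, genes=genes, lower_bound=lb,
                                upper_bound=ub)
        else:
            keep[key] = replace(rxn, stoichiometry=dict(rxn.stoichiometry))
            order.append(key)
    out = model.copy()
    out.reactions = [keep[k] for k in order]
    out._index()
    out.validate_designations()
    return out


def swap_biomass(model: MetabolicModel, new_composition: BiomassComposition,
                 gam: float | None = None,
                 id_mapping: dict[str, str] | None = None) -> MetabolicModel:
    """Replace the biomass reaction with one built from another composition.

    ``id_mapping`` translates the composition's precursor ids to this model's
    metabolite ids.  GAM is preserved unless overridden.  Unmapped precursors
    raise with the list of offending ids.
    """
    out = model.copy()
    comp = new_composition
    if id_mapping:
        comp = BiomassComposition(
            fractions=dict(comp.fractions),
            precursors={macro: {id_mapping.get(mid, mid): v
                                for mid, v in prec.items()}
                        for macro, prec in comp.precursors.items()},
            name=comp.name)
    met_map = {m.id: m for m in out.metabolites
               if m.id != _biomass_product_id(out)}
    old = out.biomass_reaction
    rxn, biomass_met = build_biomass_reaction(
        comp, met_map, gam=model.gam if gam is None else gam,
        biomass_met_id=_biomass_product_id(out),
        reaction_id=old.id)
    out.metabolites = [biomass_met if m.id == biomass_met.id else m
                       for m in out.metabolites]
    out.reactions = [rxn if r.id == old.id else r for r in out.reactions]
    if gam is not None:
        out.gam = gam
    out._index()
    out.validate_designations()
    return out


def _biomass_product_id(model: MetabolicModel) -> str:
    rxn = model.biomass_reaction
    return max(((m, c) for m, c in rxn.stoichiometry.items()
                if model.metabolite(m).is_extracellular and c > 0),
               key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# JSON dump
# ---------------------------------------------------------------------------

def model_to_json(model: MetabolicModel) -> str:
    payload = {
        "id": model.id,
        "gam": model.gam,
        "biomass_reaction_id": model.biomass_reaction_id,
        "maintenance_reaction_id": model.maintenance_reaction_id,
        "storage_exchange_ids": list(model.storage_exchange_ids),
        "metabolites": [{
            "id": m.id, "name": m.name, "formula": m.formula,
            "charge": m.charge, "compartment": m.compartment,
        } for m in model.metabolites],
        "reactions": [{
            "id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
            "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
            "genes": list(r.genes), "subsystem": r.subsystem, "kind": r.kind,
        } for r in model.reactions],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def model_from_json(text: str) -> MetabolicModel:
    d = json.loads(text)
    return MetabolicModel(
        metabolites=[Metabolite(**m) for m in d["metabolites"]],
        reactions=[Reaction(id=r["id"], name=r["name"],
                            stoichiometry=r["stoichiometry"],
                            lower_bound=r["lower_bound"],
                            upper_bound=r["upper_bound"],
                            genes=tuple(r["genes"]),
                            subsystem=r["subsystem"], kind=r["kind"])
                   for r in d["reactions"]],
        biomass_reaction_id=d["biomass_reaction_id"],
        maintenance_reaction_id=d["maintenance_reaction_id"],
        storage_exchange_ids=tuple(d["storage_exchange_ids"]),
        gam=d["gam"], id=d["id"])


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write SBML L3V1 with the FBC v2 package (bounds + growth objective)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in ("c", "e"):
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.is_extracellular)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(int(round(met.charge)))
        if met.formula is not None and all(
                abs(v - round(v)) < 1e-9 for v in met.formula.values()):
            splug.setChemicalFormula(format_formula(
                {k: round(v) for k, v in met.formula.items()}))

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(f"R_{rxn.id}")
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.reversible)
        for mid, coeff in rxn.stoichiometry.items():
            ref = (sr.createReactant() if coeff < 0 else sr.createProduct())
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        sr.appendAnnotation(
            f'<storflux xmlns="https://storflux.invalid/ns" kind="{rxn.kind}"'
            f' genes="{";".join(rxn.genes)}"/>')

    if model.biomass_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj_growth")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{model.biomass_reaction_id}")
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj_growth")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str, biomass_reaction_id: str = "",
              maintenance_reaction_id: str = "",
              storage_exchange_ids: tuple[str, ...] = ()) -> MetabolicModel:
    """Read an SBML L3 (FBC) file written by :func:`write_sbml` or similar.

    Designated reactions are recovered from the embedded annotations when
    present, else from the explicit arguments.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelFormatError(
            f"SBML errors in {path}: "
            f"{doc.getErrorLog().toString()[:500]}")
    sm = doc.getModel()

    metabolites = []
    for sp in sm.getListOfSpecies():
        splug = sp.getPlugin("fbc")
        formula = None
        charge = 0.0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = float(splug.getCharge())
        metabolites.append(Metabolite(
            id=sp.getId().removeprefix("M_"), name=sp.getName(),
            formula=formula, charge=charge,
            compartment=sp.getCompartment()))

    params = {p.getId(): p.getValue()
              for p in sm.getListOfParameters()}
    reactions = []
    biomass_id, maintenance_id = biomass_reaction_id, maintenance_reaction_id
    storage_ids = list(storage_exchange_ids)
    for sr in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(),
                        -BIG_BOUND if sr.getReversible() else 0.0) \
            if rplug else (-BIG_BOUND if sr.getReversible() else 0.0)
        ub = params.get(rplug.getUpperFluxBound(), BIG_BOUND) if rplug \
            else BIG_BOUND
        kind, genes = "conversion", ()
        ann = sr.getAnnotationString() or ""
        m = re.search(r'<storflux[^>]*\bkind="([^"]*)"', ann)
        if m:
            kind = m.group(1)
        mg = re.search(r'<storflux[^>]*\bgenes="([^"]*)"', ann)
        if mg:
            genes = tuple(g for g in mg.group(1).split(";") if g)
        rid = sr.getId().removeprefix("R_")
        reactions.append(Reaction(
            id=rid, name=sr.getName(), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, genes=genes, kind=kind))
        if kind == "biomass" and not biomass_reaction_id:
            biomass_id = rid
        elif kind == "maintenance" and not maintenance_reaction_id:
            maintenance_id = rid
        elif kind == "storage_exchange" and not storage_exchange_ids:
            storage_ids.append(rid)

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions,
        biomass_reaction_id=biomass_id,
        maintenance_reaction_id=maintenance_id,
        storage_exchange_ids=tuple(storage_ids),
        id=sm.getId() or "model")
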