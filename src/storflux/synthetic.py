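"""Synthetic toy study: a small balanced network plus noisy measurements.

The toy model is a ~30-reaction caricature of an aerobic heterotroph that can
grow on glucose or acetate and, once nitrogen runs out, divert carbon into
four storage polymers: glycogen (from glucose-6-P), PHB and PHV (from
acetyl-CoA / propionyl-CoA) and TAG (from acyl chains + glycerol-3-P).  It
contains lumped glycolysis and gluconeogenesis, pyruvate dehydrogenase, a
lumped TCA cycle, the glyoxylate shunt (the only route to net C4 from C2, so
acetate growth requires it), pyruvate carboxylase anaplerosis, oxidative
phosphorylation at a fixed P/O ratio of 2 (1 for FADH2), an ATP maintenance
reaction, and one deliberate futile cycle (a PFK/FBPase pair around a
dead-end fructose-1,6-P2 pool) that lets simulations dissipate surplus ATP.

Every conversion reaction is elementally and charge balanced; the biomass
reaction is balanced by construction (its product's formula is derived from
the precursor demand), so the exchange fluxes of any steady-state solution
close the C/N/P/COD balances exactly -- which is what makes the generated
measurement tables a valid ground truth for the reconciliation module.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .model import (BiomassComposition, MetabolicModel, Metabolite, Reaction,
                    build_biomass_reaction, cod_weight_signed)
from .fba import BIG_BOUND, Environment, FluxVector

__all__ = [
    "make_toy_model",
    "toy_biomass_composition",
    "toy_environments",
    "make_rate_measurements",
    "make_study_scenario",
    "StudyScenario",
    "toy_model_checksum",
]

# -- metabolite table (formula, charge, compartment) -------------------------

_METS: dict[str, tuple[dict[str, int], int, str, str]] = {
    # intracellular
    "glc_c":    ({"C": 6, "H": 12, "O": 6}, 0, "c", "D-glucose"),
    "ac_c":     ({"C": 2, "H": 3, "O": 2}, -1, "c", "acetate"),
    "g6p_c":    ({"C": 6, "H": 11, "O": 9, "P": 1}, -2, "c", "glucose 6-phosphate"),
    "fdp_c":    ({"C": 6, "H": 10, "O": 12, "P": 2}, -4, "c", "fructose 1,6-bisphosphate"),
    "pyr_c":    ({"C": 3, "H": 3, "O": 3}, -1, "c", "pyruvate"),
    "accoa_c":  ({"C": 23, "H": 34, "N": 7, "O": 17, "P": 3, "S": 1}, -4, "c", "acetyl-CoA"),
    "coa_c":    ({"C": 21, "H": 32, "N": 7, "O": 16, "P": 3, "S": 1}, -4, "c", "coenzyme A"),
    "ppcoa_c":  ({"C": 24, "H": 36, "N": 7, "O": 17, "P": 3, "S": 1}, -4, "c", "propanoyl-CoA"),
    "oaa_c":    ({"C": 4, "H": 2, "O": 5}, -2, "c", "oxaloacetate"),
    "glyc3p_c": ({"C": 3, "H": 7, "O": 6, "P": 1}, -2, "c", "glycerol 3-phosphate"),
    "pal_c":    ({"C": 16, "H": 31, "O": 2}, -1, "c", "palmitate"),
    "nad_c":    ({"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}, -1, "c", "NAD+"),
    "nadh_c":   ({"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}, -2, "c", "NADH"),
    "fad_c":    ({"C": 27, "H": 31, "N": 9, "O": 15, "P": 2}, -2, "c", "FAD"),
    "fadh2_c":  ({"C": 27, "H": 33, "N": 9, "O": 15, "P": 2}, -2, "c", "FADH2"),
    "atp_c":    ({"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, -4, "c", "ATP"),
    "adp_c":    ({"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, -3, "c", "ADP"),
    "pi_c":     ({"H": 1, "O": 4, "P": 1}, -2, "c", "phosphate"),
    "nh4_c":    ({"H": 4, "N": 1}, 1, "c", "ammonium"),
    "o2_c":     ({"O": 2}, 0, "c", "oxygen"),
    "co2_c":    ({"C": 1, "O": 2}, 0, "c", "carbon dioxide"),
    "h_c":      ({"H": 1}, 1, "c", "proton"),
    "h2o_c":    ({"H": 2, "O": 1}, 0, "c", "water"),
    "glycogen_c": ({"C": 6, "H": 10, "O": 5}, 0, "c", "glycogen (glucosyl unit)"),
    "phb_c":    ({"C": 4, "H": 6, "O": 2}, 0, "c", "PHB (monomer unit)"),
    "phv_c":    ({"C": 5, "H": 8, "O": 2}, 0, "c", "PHV (monomer unit)"),
    "tag_c":    ({"C": 51, "H": 98, "O": 6}, 0, "c", "triacylglycerol (tripalmitin)"),
    # extracellular
    "glc_e":    ({"C": 6, "H": 12, "O": 6}, 0, "e", "D-glucose (ext)"),
    "ac_e":     ({"C": 2, "H": 3, "O": 2}, -1, "e", "acetate (ext)"),
    "nh4_e":    ({"H": 4, "N": 1}, 1, "e", "ammonium (ext)"),
    "pi_e":     ({"H": 1, "O": 4, "P": 1}, -2, "e", "phosphate (ext)"),
    "o2_e":     ({"O": 2}, 0, "e", "oxygen (ext)"),
    "co2_e":    ({"C": 1, "O": 2}, 0, "e", "carbon dioxide (ext)"),
    "h_e":      ({"H": 1}, 1, "e", "proton (ext)"),
    "h2o_e":    ({"H": 2, "O": 1}, 0, "e", "water (ext)"),
    # storage pools are exported in polymer blocks of comparable molar mass
    # (12 glucosyl / 16 PHB / 12 PHV monomers vs 1 TAG), so that one unit of
    # any storage exchange flux carries a similar amount of COD
    "glycogen_e": ({"C": 72, "H": 120, "O": 60}, 0, "e", "glycogen pool (12-mer block)"),
    "phb_e":    ({"C": 64, "H": 96, "O": 32}, 0, "e", "PHB pool (16-mer block)"),
    "phv_e":    ({"C": 60, "H": 96, "O": 24}, 0, "e", "PHV pool (12-mer block)"),
    "tag_e":    ({"C": 51, "H": 98, "O": 6}, 0, "e", "TAG pool"),
}

# -- conversion reactions (all elementally and charge balanced) --------------

_CONVERSIONS: list[tuple[str, str, dict[str, float], bool]] = [
    ("HEX", "hexokinase",
     {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, False),
    ("GLYC", "glycolysis (g6p -> 2 pyruvate), lumped",
     {"g6p_c": -1, "nad_c": -2, "adp_c": -3, "pi_c": -2,
      "pyr_c": 2, "nadh_c": 2, "atp_c": 3, "h2o_c": 2, "h_c": 1}, False),
    ("GNG", "gluconeogenesis (2 oaa -> g6p), lumped",
     {"oaa_c": -2, "atp_c": -4, "nadh_c": -2, "h2o_c": -3, "h_c": -2,
      "g6p_c": 1, "co2_c": 2, "adp_c": 4, "nad_c": 2, "pi_c": 3}, False),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
      "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, False),
    ("PC", "pyruvate carboxylase (anaplerosis)",
     {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
      "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2}, False),
    ("TCA", "TCA cycle (acetyl-CoA oxidation), lumped",
     {"accoa_c": -1, "nad_c": -3, "fad_c": -1, "adp_c": -1, "pi_c": -1,
      "h2o_c": -2, "coa_c": 1, "co2_c": 2, "nadh_c": 3, "fadh2_c": 1,
      "atp_c": 1, "h_c": 2}, False),
    ("GLYOX", "glyoxylate shunt (2 acetyl-CoA -> oxaloacetate), lumped",
     {"accoa_c": -2, "nad_c": -2, "fad_c": -1, "h2o_c": -3,
      "oaa_c": 1, "coa_c": 2, "nadh_c": 2, "fadh2_c": 1, "h_c": 4}, False),
    ("ACS", "acetate activation (ackA/pta lump)",
     {"ac_c": -1, "atp_c": -1, "coa_c": -1,
      "accoa_c": 1, "adp_c": 1, "pi_c": 1}, False),
    ("NADHOX", "NADH oxidation via respiratory chain (P/O = 2)",
     {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2, "h_c": -3,
      "nad_c": 1, "atp_c": 2, "h2o_c": 3}, False),
    ("FADHOX", "FADH2 oxidation via respiratory chain (P/O = 1)",
     {"fadh2_c": -1, "o2_c": -0.5, "adp_c": -1, "pi_c": -1, "h_c": -1,
      "fad_c": 1, "atp_c": 1, "h2o_c": 2}, False),
    ("G3PS", "glycerol-3-phosphate synthesis (from half a hexose)",
     {"g6p_c": -0.5, "atp_c": -0.5, "nadh_c": -1, "h_c": -0.5,
      "glyc3p_c": 1, "adp_c": 0.5, "nad_c": 1}, False),
    ("PFK", "phosphofructokinase (futile-cycle leg)",
     {"g6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, False),
    ("FBP", "fructose bisphosphatase (futile-cycle leg)",
     {"fdp_c": -1, "h2o_c": -1, "g6p_c": 1, "pi_c": 1}, False),
    ("GLGS", "glycogen synthesis (via ADP-glucose), lumped",
     {"g6p_c": -1, "glycogen_c": 1, "pi_c": 1}, False),
    ("FAS", "fatty-acid synthesis (palmitate), lumped",
     {"accoa_c": -8, "nadh_c": -14, "atp_c": -7, "h_c": -6, "h2o_c": -1,
      "pal_c": 1, "coa_c": 8, "nad_c": 14, "adp_c": 7, "pi_c": 7}, False),
    ("PPCS", "propanoyl-CoA synthesis from pyruvate, lumped",
     {"pyr_c": -1, "coa_c": -1, "nadh_c": -2, "h_c": -3,
      "ppcoa_c": 1, "nad_c": 2, "h2o_c": 2}, False),
    ("PHBS", "PHB polymerisation from acetyl-CoA",
     {"accoa_c": -2, "nadh_c": -1, "h_c": -1,
      "phb_c": 1, "coa_c": 2, "nad_c": 1}, False),
    ("PHVS", "PHV polymerisation from acetyl-CoA + propanoyl-CoA",
     {"accoa_c": -1, "ppcoa_c": -1, "nadh_c": -1, "h_c": -1,
      "phv_c": 1, "coa_c": 2, "nad_c": 1}, False),
    ("TAGS", "TAG assembly from glycerol-3-P and acyl chains",
     {"glyc3p_c": -1, "pal_c": -3, "h_c": -3,
      "tag_c": 1, "pi_c": 1, "h2o_c": 2}, False),
]

_TRANSPORTS: list[tuple[str, str, str]] = [
    ("T_glc", "glc_e", "glc_c"),
    ("T_ac", "ac_e", "ac_c"),
]

# exchange reactions, written in the export direction (uptake = negative)
_EXCHANGES: list[tuple[str, str, float, float]] = [
    ("EX_glc", "glc_c", 0.0, BIG_BOUND),
    ("EX_ac", "ac_c", 0.0, BIG_BOUND),
    ("EX_nh4", "nh4_c", 0.0, BIG_BOUND),
    ("EX_pi", "pi_c", 0.0, BIG_BOUND),
    ("EX_o2", "o2_c", -BIG_BOUND, BIG_BOUND),
    ("EX_co2", "co2_c", -BIG_BOUND, BIG_BOUND),
    ("EX_h", "h_c", -BIG_BOUND, BIG_BOUND),
    ("EX_h2o", "h2o_c", -BIG_BOUND, BIG_BOUND),
]

_STORAGE_EXCHANGES: list[tuple[str, str, str, float]] = [
    ("SEC_glycogen", "glycogen_c", "glycogen_e", 12.0),
    ("SEC_phb", "phb_c", "phb_e", 16.0),
    ("SEC_phv", "phv_c", "phv_e", 12.0),
    ("SEC_tag", "tag_c", "tag_e", 1.0),
]

GAM_DEFAULT = 30.0  # mmol-ATP per g-DW

#: ATP hydrolysis overhead folded into the polymer-assembly lumps, mol-ATP
#: per mol of product (activation and polymerisation costs not resolved by
#: the lumped pathways).  The values set a deliberate COD-efficiency
#: ordering at the N-limited optimum: TAG is the single most efficient sink,
#: with PHA ~0.5 % behind and glycogen (on glucose) ~2 % behind -- a
#: near-degenerate optimal face that emulates the pathway redundancy of
#: genome-scale networks.  Vertex (simplex) solutions of the
#: storage-maximisation LP therefore report a single compound, while
#: MOMA-based selection inside the near-optimal band recovers mixtures.
GLGS_ATP_COST = 0.0
TAGS_ATP_COST = 8.0
PHA_POLY_ATP_COST = 2.1

_ATP_HYDROLYSIS = {"atp_c": -1.0, "h2o_c": -1.0,
                   "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}


def _with_atp_cost(stoich: dict[str, float], cost: float) -> dict[str, float]:
    out = dict(stoich)
    for mid, c in _ATP_HYDROLYSIS.items():
        out[mid] = out.get(mid, 0.0) + cost * c
    return {k: v for k, v in out.items() if abs(v) > 1e-12}


def toy_biomass_composition(lipid_scale: float = 1.0) -> BiomassComposition:
    """Five-macromolecule biomass of the toy organism (g/g-DW).

    ``lipid_scale`` rescales the lipid fraction (other fractions renormalised)
    for biomass-substitution experiments.
    """
    fractions = {"protein": 0.45, "carbohydrate": 0.15, "lipid": 0.15,
                 "nucleic_acid": 0.10, "small_molecules": 0.05,
                 "storage_inclusions": 0.10}
    if lipid_scale != 1.0:
        lipid = fractions["lipid"] * lipid_scale
        other = 1.0 - lipid
        scale = other / (1.0 - fractions["lipid"])
        fractions = {k: (lipid if k == "lipid" else v * scale)
                     for k, v in fractions.items()}
    precursors = {
        # mmol per g of macromolecule; negative = by-product.  Carbohydrate
        # is drawn from the glycogen pool and lipid from palmitoyl chains +
        # glycerol-3-P so that the growth reference carries flux through the
        # storage branch points (cells build these polymers during growth
        # too, which is what seeds the MOMA overflow into a storage mixture).
        "protein": {"pyr_c": 5.0, "oaa_c": 4.0, "accoa_c": 1.0, "nh4_c": 10.0,
                    "nadh_c": 6.0, "coa_c": -1.0, "nad_c": -6.0},
        "carbohydrate": {"glycogen_c": 6.17},
        "lipid": {"pal_c": 2.66, "glyc3p_c": 1.33},
        "nucleic_acid": {"g6p_c": 3.0, "oaa_c": 3.0, "nh4_c": 11.0,
                         "pi_c": 6.0, "nadh_c": 2.0, "nad_c": -2.0},
        "small_molecules": {"accoa_c": 12.0, "pyr_c": 3.0, "nh4_c": 1.0,
                            "pi_c": 0.5, "nadh_c": 20.0,
                            "coa_c": -12.0, "nad_c": -20.0},
        # PHA granules carried by growing cells: this organism class stores
        # polymer even during balanced growth, so the granule pool is a
        # biomass constituent and the growth reference carries PHB synthesis
        # flux
        "storage_inclusions": {"phb_c": 11.6},
    }
    return BiomassComposition(fractions=fractions, precursors=precursors,
                              name="toy" if lipid_scale == 1.0
                              else f"toy(lipid x{lipid_scale:g})")


def make_toy_model(gam: float = GAM_DEFAULT,
                   composition: BiomassComposition | None = None,
                   include_glyoxylate_shunt: bool = True) -> MetabolicModel:
    """Build the pinned toy metabolic model.

    The network is version-pinned: tests assert a checksum of its canonical
    serialisation, so any change here is a deliberate, visible event.
    """
    mets = [Metabolite(id=mid, name=name, formula=dict(f), charge=ch,
                       compartment=comp)
            for mid, (f, ch, comp, name) in _METS.items()]
    met_map = {m.id: m for m in mets}

    rxns: list[Reaction] = []
    for rid, name, stoich, reversible in _CONVERSIONS:
        if rid == "GLYOX" and not include_glyoxylate_shunt:
            continue
        if rid == "GLGS":
            stoich = _with_atp_cost(stoich, GLGS_ATP_COST)
        elif rid == "TAGS":
            stoich = _with_atp_cost(stoich, TAGS_ATP_COST)
        elif rid in ("PHBS", "PHVS"):
            stoich = _with_atp_cost(stoich, PHA_POLY_ATP_COST)
        rxns.append(Reaction(id=rid, name=name, stoichiometry=dict(stoich),
                             lower_bound=-BIG_BOUND if reversible else 0.0,
                             upper_bound=BIG_BOUND, kind="conversion"))
    for rid, src, dst in _TRANSPORTS:
        rxns.append(Reaction(id=rid, name=f"{src} transport",
                             stoichiometry={src: -1.0, dst: 1.0},
                             lower_bound=-BIG_BOUND, upper_bound=BIG_BOUND,
                             kind="transport"))
    for rid, met_c, lb, ub in _EXCHANGES:
        met_e = met_c.replace("_c", "_e")
        rxns.append(Reaction(id=rid, name=f"{met_c} exchange",
                             stoichiometry={met_c: -1.0, met_e: 1.0},
                             lower_bound=lb, upper_bound=ub, kind="exchange"))
    for rid, met_c, met_e, block in _STORAGE_EXCHANGES:
        rxns.append(Reaction(id=rid, name=f"{met_c} storage export",
                             stoichiometry={met_c: -block, met_e: 1.0},
                             lower_bound=0.0, upper_bound=BIG_BOUND,
                             kind="storage_exchange"))
    rxns.append(Reaction(id="MAINT", name="ATP maintenance",
                         stoichiometry={"atp_c": -1, "h2o_c": -1,
                                        "adp_c": 1, "pi_c": 1, "h_c": 1},
                         lower_bound=0.0, upper_bound=BIG_BOUND,
                         kind="maintenance"))

    comp = composition or toy_biomass_composition()
    biomass_rxn, biomass_met = build_biomass_reaction(comp, met_map, gam=gam)
    rxns.append(biomass_rxn)
    mets.append(biomass_met)

    # transports and exchanges for glc/ac are redundant routes; drop the plain
    # transports so each substrate has a single boundary flux
    rxns = [r for r in rxns if r.id not in ("T_glc", "T_ac")]

    return MetabolicModel(
        metabolites=mets, reactions=rxns,
        biomass_reaction_id="BIOMASS", maintenance_reaction_id="MAINT",
        storage_exchange_ids=("SEC_glycogen", "SEC_phb", "SEC_phv", "SEC_tag"),
        gam=gam, id="toy_storage")


def toy_model_checksum(model: MetabolicModel) -> str:
    """SHA-256 of a canonical serialisation (pins the network version)."""
    payload = {
        "metabolites": sorted(
            (m.id, sorted((m.formula or {}).items()), round(m.charge, 9),
             m.compartment) for m in model.metabolites),
        "reactions": sorted(
            (r.id, sorted((k, round(v, 9)) for k, v in r.stoichiometry.items()),
             round(r.lower_bound, 9), round(r.upper_bound, 9), r.kind)
            for r in model.reactions),
        "gam": model.gam,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


# -- study conditions --------------------------------------------------------

#: Measured-like uptake rates, mmol/(g-DW.h).  Acetate is consumed faster
#: than glucose and the N-limited substrate uptake is 14 % of the non-limited
#: one, mirroring the physiology the toy study emulates.
STUDY_UPTAKES = {
    "glucose": {"exchange": "EX_glc", "growth": 2.0, "limited": 0.28,
                "o2_limited": 0.5},
    "acetate": {"exchange": "EX_ac", "growth": 6.0, "limited": 0.84,
                "o2_limited": 0.75},
}

#: Carbon-source-dependent pathway repression applied in both culture
#: phases: gluconeogenesis is catabolite-repressed when glucose is the
#: substrate.  (On acetate the gluconeogenic route must of course stay
#: open.)  Without this regulatory constraint the N-limited MOMA solutions
#: run a large glycolysis/gluconeogenesis carbon-recycling loop that mimics
#: the growth flux profile instead of storing.
SUBSTRATE_REPRESSION = {
    "glucose": {"GNG": 0.0},
    "acetate": {},
}

NGAM_GROWTH_DEFAULT = 0.5  # mmol/(g-DW.h) during the non-limited phase

#: Measured-like storage accumulation during balanced growth: cells already
#: store ~10 % of the consumed substrate COD in the non-limited phase, in a
#: glycogen/PHA/TAG mixture.  These rates are pinned in the growth
#: environment, so the MOMA reference carries flux through every storage
#: export.  Both substrates are consumed at 384 mg-COD/(g-DW.h), and the
#: polymer export blocks all carry ~2.3 g-COD/mmol, so the same block rates
#: serve both substrates.
GROWTH_STORAGE_COD_FRACTION = 0.10
GROWTH_STORAGE_SPLIT = {"glycogen": 0.35, "pha": 0.45, "tag": 0.20}
_BLOCK_COD = {"SEC_glycogen": 2304.0, "SEC_phb": 2304.0,
              "SEC_phv": 2304.0, "SEC_tag": 2320.0}  # mg-O2 per mmol block


def growth_storage_rates(substrate: str = "glucose",
                         phb_phv_cod_ratio: float = 0.85) -> dict[str, float]:
    """Pinned storage export rates (mmol block/(g-DW.h)) during growth."""
    spec = STUDY_UPTAKES[substrate]
    cod_in = spec["growth"] * (192.0 if substrate == "glucose" else 64.0)
    total = GROWTH_STORAGE_COD_FRACTION * cod_in
    split = GROWTH_STORAGE_SPLIT
    return {
        "SEC_glycogen": total * split["glycogen"] / _BLOCK_COD["SEC_glycogen"],
        "SEC_phb": total * split["pha"] * phb_phv_cod_ratio
        / _BLOCK_COD["SEC_phb"],
        "SEC_phv": total * split["pha"] * (1 - phb_phv_cod_ratio)
        / _BLOCK_COD["SEC_phv"],
        "SEC_tag": total * split["tag"] / _BLOCK_COD["SEC_tag"],
    }


def toy_environments(substrate: str = "glucose",
                     ngam_growth: float = NGAM_GROWTH_DEFAULT,
                     ngam_limited: float = 1.5,
                     storage_in_growth: bool = True,
                     ) -> tuple[Environment, Environment]:
    """(non-limited growth, N-limited) environment pair for one substrate.

    ``storage_in_growth`` pins the measured growth-phase storage accumulation
    rates in the non-limited environment (set False for a storage-free
    growth reference).
    """
    try:
        spec = STUDY_UPTAKES[substrate]
    except KeyError:
        raise ValueError(f"unknown substrate {substrate!r}") from None
    repression = SUBSTRATE_REPRESSION[substrate]
    fixed = dict(repression)
    if storage_in_growth:
        fixed.update(growth_storage_rates(substrate))
    env_growth = Environment(
        substrate_exchange=spec["exchange"], substrate_uptake=spec["growth"],
        nh4_uptake=10.0, pi_uptake=10.0, ngam=ngam_growth,
        fixed_rates=fixed)
    env_limited = Environment(
        substrate_exchange=spec["exchange"], substrate_uptake=spec["limited"],
        nh4_uptake=0.0, pi_uptake=10.0, ngam=ngam_limited,
        o2_unlimited=False, o2_uptake=spec["o2_limited"],
        fixed_rates=dict(repression))
    return env_growth, env_limited


# -- measurement generators --------------------------------------------------

#: Exchange fluxes reported in a measured-rate table, with biomass.
_MEASURED_SPECIES = {
    "glucose": "EX_glc", "acetate": "EX_ac", "o2": "EX_o2", "co2": "EX_co2",
    "nh4": "EX_nh4", "pi": "EX_pi",
    "glycogen": "SEC_glycogen", "phb": "SEC_phb", "phv": "SEC_phv",
    "tag": "SEC_tag",
}


def make_rate_measurements(model: MetabolicModel, true_fluxes: FluxVector,
                           rel_sd: float = 0.05, seed: int = 0,
                           substrate: str = "glucose"):
    """Noisy measured conversion rates from a true flux distribution.

    Perturbs each reported exchange rate with independent Gaussian noise of
    relative standard deviation ``rel_sd`` (true covariance recorded in the
    table).  ``rel_sd = 0`` reproduces the exact balanced rates.  Rates are
    signed: consumption negative.  Returns a
    :class:`storflux.reconciliation.MeasuredRates`.
    """
    from .reconciliation import MeasuredRates, composition_matrix

    if rel_sd < 0:
        raise ValueError("rel_sd must be >= 0")
    rng = np.random.default_rng(seed)
    species, rates, true_rates, sds = [], [], [], []
    items = {k: v for k, v in _MEASURED_SPECIES.items()
             if k not in ({"glucose", "acetate"} - {substrate})}
    items["biomass"] = model.biomass_reaction_id
    for name, rid in items.items():
        v = true_fluxes.get(rid, 0.0)
        if rid.startswith("EX_"):
            v = -(-v)  # exchange already signed: export positive
        if name == "biomass":
            # report biomass formation in mmol of biomass unit /(g-DW.h)
            rxn = model.reaction(rid)
            coeff = next(c for mid, c in rxn.stoichiometry.items()
                         if c > 0 and model.metabolite(mid).is_extracellular)
            v = v * coeff
        sd = rel_sd * max(abs(v), 1e-3)
        noisy = v + rng.normal(0.0, sd) if rel_sd > 0 else v
        species.append(name)
        true_rates.append(v)
        rates.append(noisy)
        sds.append(sd if rel_sd > 0 else 1e-6)
    comp = composition_matrix(model, species, items)
    return MeasuredRates(
        species=species, rates=np.array(rates),
        covariance=np.diag(np.array(sds) ** 2), composition=comp,
        true_rates=np.array(true_rates))


@dataclass
class StudyScenario:
    """A synthetic glucose/acetate storage study with known ground truth."""

    substrate: str
    env_growth: Environment
    env_limited: Environment
    generating_objective: str
    ngam_true: float
    true_yields: dict[str, float]          # glycogen/PHA/TAG fractions
    true_total: float                      # mg-COD/(g-COD biomass . h)
    measured_yields: "object"              # discrimination.ExperimentalYields


def make_study_scenario(substrate: str = "glucose",
                        generating_objective: str = "max_storage_env_moma",
                        ngam_true: float = 1.5, rel_sd: float = 0.1,
                        seed: int = 0, model: MetabolicModel | None = None,
                        ) -> StudyScenario:
    """Forward-simulate a storage study and add measurement noise.

    The generating objective is run on the toy model to obtain true storage
    yield fractions; Gaussian noise (relative SD ``rel_sd``, floored at an
    absolute SE of 0.02 and truncated at 0) produces the "measured" yields.
    """
    from .discrimination import ExperimentalYields
    from .objectives import ObjectiveSpec, predict_storage

    mdl = model if model is not None else make_toy_model()
    env_growth, env_limited = toy_environments(substrate,
                                               ngam_limited=ngam_true)
    pred = predict_storage(mdl, env_growth, env_limited,
                           ObjectiveSpec(generating_objective), ngam=ngam_true)
    if not pred.optimal:
        raise RuntimeError(
            f"generating objective {generating_objective} infeasible")
    truth = pred.merged_fractions()
    rng = np.random.default_rng(seed)
    measured, se = {}, {}
    for compound, frac in truth.items():
        sd = max(rel_sd * frac, 0.02)
        measured[compound] = max(0.0, frac + (rng.normal(0.0, sd)
                                              if rel_sd > 0 else 0.0))
        se[compound] = sd
    yields = ExperimentalYields(
        yields={substrate: measured}, se={substrate: se})
    return StudyScenario(
        substrate=substrate, env_growth=env_growth, env_limited=env_limited,
        generating_objective=generating_objective, ngam_true=ngam_true,
        true_yields=truth, true_total=pred.total_storage_flux,
        measured_yields=yields)
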