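"""Tabular/SBML/JSON model I/O, deduplication, biomass swapping."""

import numpy as np
import pytest

from storflux.fba import fba_max_growth
from storflux.model import build_stoich_matrix
from storflux.model_io import (ModelFormatError, ModelReferenceError,
                               deduplicate_reactions, load_model_tables,
                               model_from_json, model_to_json,
                               parse_equation, read_sbml, swap_biomass,
                               write_model_tables, write_sbml)
from storflux.synthetic import (make_toy_model, toy_biomass_composition,
                                toy_environments)


class TestEquationParsing:
    @pytest.mark.parametrize("eq,stoich,rev", [
        ("A + 2 B <=> C", {"A": -1, "B": -2, "C": 1}, True),
        ("g6p <=> f6p", {"g6p": -1, "f6p": 1}, True),
        ("a -> b", {"a": -1, "b": 1}, False),
        ("0.5 x + y --> 1.5 z", {"x": -0.5, "y": -1, "z": 1.5}, False),
        ("a ->", {"a": -1}, False),
    ])
    def test_examples(self, eq, stoich, rev):
        got, reversible = parse_equation(eq)
        assert got == pytest.approx(stoich)
        assert reversible is rev

    def test_no_arrow_rejected(self):
        with pytest.raises(ModelFormatError, match="arrow"):
            parse_equation("a + b = c")


def _write_tables(tmp_path, rxn_text, met_text):
    rxn = tmp_path / "rxns.tsv"
    met = tmp_path / "mets.tsv"
    rxn.write_text(rxn_text)
    met.write_text(met_text)
    return rxn, met


TOY_RXN_TABLE = (
    "id\tequation\tdirectionality\tkind\tgenes\n"
    "UPT\ts_e -> s_c\tirreversible\texchange\t\n"
    "ISO\ts_c <=> p_c\treversible\tconversion\torf1;orf2\n"
    "SEC\tp_c -> p_e\tirreversible\texchange\t\n")
TOY_MET_TABLE = (
    "id\tformula\tcharge\tcompartment\n"
    "s_e\tC6H12O6\t0\te\n"
    "s_c\tC6H12O6\t0\tc\n"
    "p_c\tC6H12O6\t0\tc\n"
    "p_e\tC6H12O6\t0\te\n")


class TestTabularLoading:
    def test_three_reaction_round_trip(self, tmp_path):
        model = load_model_tables(*_write_tables(tmp_path, TOY_RXN_TABLE,
                                                 TOY_MET_TABLE))
        assert len(model.reactions) == 3
        iso = model.reaction("ISO")
        assert iso.stoichiometry == {"s_c": -1, "p_c": 1}
        assert iso.genes == ("orf1", "orf2")

    def test_reversible_directionality_sets_negative_lower_bound(self,
                                                                 tmp_path):
        model = load_model_tables(*_write_tables(tmp_path, TOY_RXN_TABLE,
                                                 TOY_MET_TABLE))
        assert model.reaction("ISO").lower_bound < 0
        assert model.reaction("UPT").lower_bound == 0.0

    def test_missing_required_column_is_format_error(self, tmp_path):
        bad = "id\tname\nR1\tfoo\n"
        with pytest.raises(ModelFormatError, match="equation"):
            load_model_tables(*_write_tables(tmp_path, bad, TOY_MET_TABLE))

    def test_unknown_metabolite_is_reference_error_listing_ids(self,
                                                               tmp_path):
        rxn = "id\tequation\nR1\tghost_c -> p_c\n"
        with pytest.raises(ModelReferenceError, match="ghost_c"):
            load_model_tables(*_write_tables(tmp_path, rxn, TOY_MET_TABLE))

    def test_unparseable_row_reported_with_row_number(self, tmp_path):
        rxn = ("id\tequation\n"
               "R1\ts_c -> p_c\n"
               "R2\tno arrow here\n")
        with pytest.raises(ModelFormatError, match="row 3"):
            load_model_tables(*_write_tables(tmp_path, rxn, TOY_MET_TABLE))


def test_toy_model_tabular_round_trip(tmp_path, toy_model):
    """Write + re-read preserves S, bounds and designations."""
    rxn, met = tmp_path / "r.tsv", tmp_path / "m.tsv"
    write_model_tables(toy_model, rxn, met)
    back = load_model_tables(rxn, met)
    assert [r.id for r in back.reactions] == [r.id for r in
                                              toy_model.reactions]
    S0, rows0 = build_stoich_matrix(toy_model)
    S1, rows1 = build_stoich_matrix(back)
    assert rows0 == rows1
    np.testing.assert_allclose(S0, S1, atol=1e-9)
    for a, b in zip(toy_model.reactions, back.reactions):
        assert a.lower_bound == pytest.approx(b.lower_bound)
        assert a.upper_bound == pytest.approx(b.upper_bound)
    assert back.biomass_reaction_id == toy_model.biomass_reaction_id
    assert back.maintenance_reaction_id == toy_model.maintenance_reaction_id
    assert tuple(back.storage_exchange_ids) == toy_model.storage_exchange_ids


def test_json_round_trip(toy_model):
    back = model_from_json(model_to_json(toy_model))
    S0, _ = build_stoich_matrix(toy_model)
    S1, _ = build_stoich_matrix(back)
    np.testing.assert_allclose(S0, S1)
    assert back.gam == toy_model.gam


def test_sbml_round_trip_preserves_flux_space(tmp_path, toy_model):
    path = tmp_path / "toy.xml"
    write_sbml(toy_model, str(path))
    back = read_sbml(str(path))
    assert len(back.reactions) == len(toy_model.reactions)
    assert back.biomass_reaction_id == toy_model.biomass_reaction_id
    env = toy_environments("glucose")[0]
    mu0 = fba_max_growth(toy_model, env).objective_value
    mu1 = fba_max_growth(back, env).objective_value
    assert mu1 == pytest.approx(mu0, rel=1e-6)


def test_sbml_growth_matches_independent_cobra_reader(tmp_path, toy_model):
    """Cross-check the toy growth FBA against cobrapy on the same SBML."""
    cobra = pytest.importorskip("cobra")
    from dataclasses import replace

    path = tmp_path / "toy.xml"
    write_sbml(toy_model, str(path))
    cm = cobra.io.read_sbml_model(str(path))
    env = replace(toy_environments("glucose", storage_in_growth=False)[0],
                  fixed_rates={"GNG": 0.0})
    # mirror the environment in cobra terms
    cm.reactions.get_by_id("EX_glc").bounds = (-2.0, -2.0)
    cm.reactions.get_by_id("EX_nh4").lower_bound = -10.0
    cm.reactions.get_by_id("EX_pi").lower_bound = -10.0
    cm.reactions.get_by_id("EX_o2").lower_bound = -1e4
    cm.reactions.get_by_id("MAINT").bounds = (0.5, 0.5)
    cm.reactions.get_by_id("GNG").bounds = (0.0, 0.0)
    cm.objective = "BIOMASS"
    mu_cobra = cm.optimize().objective_value
    mu_ours = fba_max_growth(toy_model, env).objective_value
    assert mu_ours == pytest.approx(mu_cobra, rel=1e-6)


class TestDeduplication:
    def test_merges_isoenzymes_and_unions_genes(self, toy_model):
        from dataclasses import replace
        m = toy_model.copy()
        dup = replace(m.reaction("PDH"),
                      id="PDH_iso",
                      stoichiometry=dict(m.reaction("PDH").stoichiometry),
                      genes=("orfB",))
        m.reactions.append(dup)
        m.reactions[m.reaction_index["PDH"]] = replace(
            m.reaction("PDH"), genes=("orfA",))
        m._index()
        out = deduplicate_reactions(m)
        assert len(out.reactions) == len(toy_model.reactions)
        assert set(out.reaction("PDH").genes) == {"orfA", "orfB"}

    def test_idempotent_on_clean_model(self, toy_model):
        once = deduplicate_reactions(toy_model)
        twice = deduplicate_reactions(once)
        assert [r.id for r in once.reactions] == [r.id for r in
                                                  twice.reactions]

    def test_mirrored_reversible_reactions_merge(self, toy_model):
        from storflux.model import Reaction
        m = toy_model.copy()
        m.reactions.append(Reaction("AB", {"g6p_c": -1, "fdp_c": 1},
                                    lower_bound=-1e4, genes=("x",)))
        m.reactions.append(Reaction("BA", {"g6p_c": 1, "fdp_c": -1},
                                    lower_bound=-1e4, genes=("y",)))
        m._index()
        out = deduplicate_reactions(m)
        assert len(out.reactions) == len(toy_model.reactions) + 1
        merged = next(r for r in out.reactions if r.id in ("AB", "BA"))
        assert set(merged.genes) == {"x", "y"}

    def test_flux_space_preserved(self, toy_model):
        from dataclasses import replace
        m = toy_model.copy()
        m.reactions.append(replace(
            m.reaction("TCA"), id="TCA_iso",
            stoichiometry=dict(m.reaction("TCA").stoichiometry)))
        m._index()
        out = deduplicate_reactions(m)
        env = toy_environments("glucose")[0]
        assert fba_max_growth(out, env).objective_value == pytest.approx(
            fba_max_growth(toy_model, env).objective_value, rel=1e-8)


class TestBiomassSwap:
    def test_identity_swap_preserves_growth(self, toy_model):
        env = toy_environments("glucose")[0]
        swapped = swap_biomass(toy_model, toy_biomass_composition())
        mu0 = fba_max_growth(toy_model, env).objective_value
        mu1 = fba_max_growth(swapped, env).objective_value
        assert mu1 == pytest.approx(mu0, rel=1e-9)

    def test_doubled_lipid_fraction_raises_acyl_chain_flux(self, toy_model):
        from storflux.objectives import nonlimited_reference
        env = toy_environments("glucose")[0]
        fat = swap_biomass(toy_model, toy_biomass_composition(lipid_scale=2.0))
        lean_ref = nonlimited_reference(toy_model, env)
        fat_ref = nonlimited_reference(fat, env)
        assert fat_ref["FAS"] > lean_ref["FAS"] * 1.05

    def test_unmapped_precursor_raises_listing_ids(self, toy_model):
        from storflux.model import BiomassComposition
        comp = BiomassComposition(
            fractions={"bulk": 1.0},
            precursors={"bulk": {"martian_c": 1.0}})
        with pytest.raises(ValueError, match="martian_c"):
            swap_biomass(toy_model, comp)
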