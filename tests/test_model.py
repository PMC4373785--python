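import numpy as np
import pytest

import limflux as lf
from limflux.model import (
    export_stoichiometric_matrix,
    gene_association_genes,
    parse_gene_association,
)


class TestStoichiometricMatrix:
    def test_toy_chain_matrix(self, toy_chain):
        E, rows, cols = lf.stoichiometric_matrix(toy_chain)
        assert rows == ["M_A", "M_B"]
        assert cols == ["R1", "R2", "R3"]
        np.testing.assert_array_equal(E, [[1, -1, 0], [0, 1, -1]])

    def test_column_order_follows_reaction_order(self, toy_chain):
        _, _, cols = lf.stoichiometric_matrix(toy_chain)
        assert cols == toy_chain.reaction_ids

    def test_empty_model(self):
        E, rows, cols = lf.stoichiometric_matrix(lf.MetabolicModel())
        assert E.shape == (0, 0) and rows == [] and cols == []

    def test_boundary_rows_excluded(self, toy_chain):
        E, rows, _ = lf.stoichiometric_matrix(toy_chain)
        assert "M_A_b" not in rows and "M_B_b" not in rows

    def test_mass_balanced_internal_columns_sum_to_zero(self):
        # fully internal isomerisation chain: every column balances
        mets = [lf.Metabolite(f"M_{i}", compartment="c") for i in range(3)]
        rxns = [lf.Reaction("Ra", {"M_0": -1, "M_1": 1}),
                lf.Reaction("Rb", {"M_1": -1, "M_2": 1})]
        E, _, _ = lf.stoichiometric_matrix(lf.MetabolicModel(mets, rxns))
        np.testing.assert_allclose(E.sum(axis=0), 0.0)

    def test_duplicate_species_references_summed(self, tmp_path):
        # one species on both sides of an SBML reaction nets out
        mets = [lf.Metabolite("M_x", compartment="c"),
                lf.Metabolite("M_y", compartment="c")]
        rxns = [lf.Reaction("R", {"M_x": -2, "M_y": 1})]
        m = lf.MetabolicModel(mets, rxns)
        p = tmp_path / "m.xml"
        lf.write_sbml(m, p)
        text = p.read_text().replace(
            '<speciesReference species="M_x" stoichiometry="2" constant="true"/>',
            '<speciesReference species="M_x" stoichiometry="1" constant="true"/>'
            '<speciesReference species="M_x" stoichiometry="1" constant="true"/>',
        )
        p.write_text(text)
        m2 = lf.read_sbml(p)
        assert m2.reaction("R").stoichiometry == {"M_x": -2.0, "M_y": 1.0}

    def test_csv_export(self, toy_chain, tmp_path):
        import pandas as pd

        p = tmp_path / "E.csv"
        export_stoichiometric_matrix(toy_chain, p)
        df = pd.read_csv(p, index_col=0)
        assert list(df.columns) == ["R1", "R2", "R3"]
        assert list(df.index) == ["M_A", "M_B"]


class TestSBMLRoundTrip:
    def test_toy_chain_counts(self, toy_chain, tmp_path):
        p = tmp_path / "toy.xml"
        lf.write_sbml(toy_chain, p)
        m = lf.read_sbml(p)
        assert len(m.reactions) == 3
        assert len(m.metabolites) == 4
        assert sum(mm.is_boundary for mm in m.metabolites) == 2

    def test_empty_model_valid(self, tmp_path):
        p = tmp_path / "empty.xml"
        lf.write_sbml(lf.MetabolicModel(), p)
        assert lf.read_sbml(p).reactions == []

    @pytest.mark.parametrize("fixture", ["toy_chain", "branched_toy"])
    def test_roundtrip_identity(self, fixture, request, tmp_path):
        model = request.getfixturevalue(fixture)
        p = tmp_path / "m.xml"
        lf.write_sbml(model, p)
        m2 = lf.read_sbml(p)
        assert m2.reaction_ids == model.reaction_ids
        for r1, r2 in zip(model.reactions, m2.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert r1.reversible == r2.reversible
            assert r1.gene_association == r2.gene_association
        assert {m.id: m.is_boundary for m in m2.metabolites} == {
            m.id: m.is_boundary for m in model.metabolites
        }
        assert m2.annotations == model.annotations

    def test_boundary_suffix_convention(self, tmp_path):
        # _b suffix marks external even without the boundaryCondition flag
        mets = [lf.Metabolite("M_glc_b", compartment="e", is_boundary=False),
                lf.Metabolite("M_glc_c", compartment="c")]
        rxns = [lf.Reaction("R", {"M_glc_b": -1, "M_glc_c": 1})]
        p = tmp_path / "m.xml"
        lf.write_sbml(lf.MetabolicModel(mets, rxns), p)
        m = lf.read_sbml(p)
        assert m.metabolite("M_glc_b").is_boundary
        assert not lf.read_sbml(p, boundary_suffix="").metabolite("M_glc_b").is_boundary

    def test_parse_failure_names_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<sbml><model><oops></model></sbml>")
        with pytest.raises(lf.FormatError, match="line"):
            lf.read_sbml(p)

    def test_undeclared_species_is_integrity_error(self, toy_chain, tmp_path):
        p = tmp_path / "m.xml"
        lf.write_sbml(toy_chain, p)
        text = p.read_text().replace('species="M_B_b"', 'species="M_ghost"')
        p.write_text(text)
        with pytest.raises((lf.ModelIntegrityError, lf.FormatError)):
            lf.read_sbml(p)


class TestSubmodelSelection:
    def test_by_pathway(self, toy_chain):
        sub = lf.select_submodel(toy_chain, pathways=["chain"])
        assert sub.reaction_ids == ["R1", "R2", "R3"]

    def test_by_reaction_id_keeps_only_referenced_metabolites(self, toy_chain):
        sub = lf.select_submodel(toy_chain, reaction_ids=["R1"])
        assert sub.reaction_ids == ["R1"]
        assert set(sub.metabolite_ids) == {"M_A_b", "M_A"}

    def test_by_gene(self, toy_chain):
        sub = lf.select_submodel(toy_chain, genes=["g1"])
        assert sub.reaction_ids == ["R1", "R2"]

    def test_all_ids_is_identity(self, toy_chain):
        sub = lf.select_submodel(toy_chain, reaction_ids=toy_chain.reaction_ids)
        assert sub.reaction_ids == toy_chain.reaction_ids
        assert sub.metabolite_ids == toy_chain.metabolite_ids

    def test_no_match_warns_and_returns_empty(self, toy_chain):
        with pytest.warns(UserWarning):
            sub = lf.select_submodel(toy_chain, pathways=["unknown"])
        assert sub.reactions == []

    def test_no_selector_is_error(self, toy_chain):
        with pytest.raises(ValueError):
            lf.select_submodel(toy_chain)


class TestRemoveReactions:
    def test_remove_one(self, toy_chain):
        m = lf.remove_reactions(toy_chain, ["R3"])
        assert m.reaction_ids == ["R1", "R2"]
        assert "M_B_b" not in m.metabolite_ids  # orphan dropped

    def test_remove_none_is_identity(self, toy_chain):
        m = lf.remove_reactions(toy_chain, [])
        assert m.reaction_ids == toy_chain.reaction_ids

    def test_remove_all(self, toy_chain):
        m = lf.remove_reactions(toy_chain, toy_chain.reaction_ids)
        assert m.reactions == [] and m.metabolites == []

    def test_unknown_id_lists_offenders(self, toy_chain):
        with pytest.raises(KeyError, match="R_nope"):
            lf.remove_reactions(toy_chain, ["R1", "R_nope"])


class TestGeneAssociations:
    def test_flattening(self):
        assert gene_association_genes("(g1 and g2) or g3") == ["g1", "g2", "g3"]

    @pytest.mark.parametrize("expr,ast", [
        ("g1", ("gene", "g1")),
        ("g1 AND g2", ("and", [("gene", "g1"), ("gene", "g2")])),
        ("g1 or (g2 and g3)",
         ("or", [("gene", "g1"), ("and", [("gene", "g2"), ("gene", "g3")])])),
    ])
    def test_parser(self, expr, ast):
        assert parse_gene_association(expr) == ast

    @pytest.mark.parametrize("bad", ["", "g1 and", "(g1 or g2", "and g1"])
    def test_malformed(self, bad):
        with pytest.raises(lf.FormatError):
            parse_gene_association(bad)

    def test_extract_map(self, toy_chain):
        assoc = lf.extract_gene_associations(toy_chain)
        assert assoc == {"R1": ["g1", "g4"], "R2": ["g1", "g2", "g3"]}

    def test_no_associations_empty_map(self, branched_toy):
        m = lf.remove_reactions(branched_toy, ["R_a", "R_b"])
        assert lf.extract_gene_associations(m) == {}

    def test_malformed_association_names_reaction(self):
        mets = [lf.Metabolite("M_x", compartment="c")]
        rxns = [lf.Reaction("R_bad", {"M_x": 1}, gene_association="g1 and")]
        with pytest.raises(lf.FormatError, match="R_bad"):
            lf.extract_gene_associations(lf.MetabolicModel(mets, rxns))


class TestInvariants:
    def test_duplicate_reaction_ids_rejected(self):
        mets = [lf.Metabolite("M_x", compartment="c")]
        rxns = [lf.Reaction("R", {"M_x": 1}), lf.Reaction("R", {"M_x": -1})]
        with pytest.raises(lf.ModelIntegrityError):
            lf.MetabolicModel(mets, rxns)

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(lf.ModelIntegrityError):
            lf.MetabolicModel([], [lf.Reaction("R", {"M_x": 1})])

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(lf.ModelIntegrityError):
            lf.Reaction("R", {})
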