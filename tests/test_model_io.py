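"""Model containers, GPR boolean logic, classification, and serialization."""

import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

import budstrain as bs
from budstrain.model_io import (
    GPR_TRUE,
    GPRExpression,
    GPRParseError,
    NotGeneDisableableError,
    SBMLError,
    SchemaError,
    model_to_dict,
)


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

class TestGPR:
    def test_isozyme_or_rule(self):
        expr = bs.parse_gpr("(ADH1 or ADH3 or ADH5)")
        assert expr.op == "or"
        assert len(expr.children) == 3
        assert expr.genes() == {"ADH1", "ADH3", "ADH5"}

    def test_empty_rule_is_always_on(self):
        expr = bs.parse_gpr("")
        assert expr.is_always_on
        assert bs.evaluate_gpr(expr, {"ANY", "GENES"})

    def test_unclosed_parenthesis_reports_position(self):
        with pytest.raises(GPRParseError) as err:
            bs.parse_gpr("(A and (B")
        assert err.value.position == 7  # the unclosed '('
        with pytest.raises(GPRParseError):
            bs.parse_gpr("(A and (B or")

    @pytest.mark.parametrize("bad", ["A and", "or B", "A B", "(A))", "A and ()"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(GPRParseError):
            bs.parse_gpr(bad)

    def test_or_semantics_isozymes_survive_partial_deletion(self):
        expr = bs.parse_gpr("ADH1 or ADH3 or ADH5")
        assert bs.evaluate_gpr(expr, {"ADH1"})
        assert not bs.evaluate_gpr(expr, {"ADH1", "ADH3", "ADH5"})

    def test_and_semantics_exhaustive_truth_table(self):
        # complex subunits: every assignment checked against python and/or
        expr = bs.parse_gpr("PDA1 and PDB1")
        for d1, d2 in itertools.product([False, True], repeat=2):
            deleted = {g for g, d in (("PDA1", d1), ("PDB1", d2)) if d}
            assert bs.evaluate_gpr(expr, deleted) == ((not d1) and (not d2))

    def test_case_insensitive_connectives(self):
        assert bs.parse_gpr("A AND B").op == "and"
        assert bs.parse_gpr("a Or b").op == "or"

    def test_dnf_of_nested_rule(self):
        expr = bs.parse_gpr("A and (B or C)")
        assert sorted(map(sorted, expr.dnf())) == [["A", "B"], ["A", "C"]]


# random GPR trees for the parse -> print -> parse idempotence property
_genes = st.sampled_from(["G1", "G2", "G3", "G4", "G5", "G6"])


def _gpr_trees(depth=3):
    leaf = st.builds(lambda g: GPRExpression(op="gene", gene=g), _genes)
    return st.recursive(
        leaf,
        lambda children: st.builds(
            lambda op, cs: GPRExpression(op=op, children=tuple(cs)),
            st.sampled_from(["and", "or"]),
            st.lists(children, min_size=2, max_size=3),
        ),
        max_leaves=8,
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_gpr_trees())
def test_parse_pretty_print_parse_is_idempotent(expr):
    printed = expr.to_string()
    reparsed = bs.parse_gpr(printed)
    assert reparsed.to_string() == printed
    assert bs.parse_gpr(reparsed.to_string()) == reparsed


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_gpr_trees(), st.sets(_genes))
def test_dnf_preserves_semantics(expr, deleted):
    # the DNF is satisfied iff some conjunct has no deleted gene
    via_dnf = any(not (conj & deleted) for conj in expr.dnf())
    assert via_dnf == expr.evaluate(deleted)


# ---------------------------------------------------------------------------
# Reaction classification
# ---------------------------------------------------------------------------

class TestClassification:
    @pytest.mark.parametrize(
        "rid,kind",
        [
            ("EX_glc_e", "exchange"),       # single-metabolite boundary
            ("GLCt", "transport"),          # same base species, two compartments
            ("ADH", "internal"),            # one compartment
            ("ATPM", "maintenance"),
            ("BIOMASS", "biomass"),
        ],
    )
    def test_fixture_kinds(self, pyrcore, rid, kind):
        assert bs.classify_reaction(pyrcore, rid) == kind

    def test_classification_partitions_reactions(self, pyrcore):
        kinds = bs.classify_all(pyrcore)
        assert set(kinds) == {r.id for r in pyrcore.reactions}
        assert set(kinds.values()) <= {
            "exchange", "transport", "internal", "biomass", "maintenance"
        }

    def test_unknown_reaction_raises(self, pyrcore):
        with pytest.raises(KeyError):
            bs.classify_reaction(pyrcore, "NOT_A_RXN")


# ---------------------------------------------------------------------------
# Minimal gene knockouts
# ---------------------------------------------------------------------------

def _brute_force_minimal_sets(model, targets):
    """Independent oracle: enumerate all subsets of the model's genes."""
    genes = sorted(model.genes)
    disabling = []
    for size in range(len(genes) + 1):
        for combo in itertools.combinations(genes, size):
            s = frozenset(combo)
            if all(not model.reaction(t).gpr.evaluate(s) for t in targets):
                disabling.append(s)
    return sorted(
        (s for s in disabling if not any(t < s for t in disabling)),
        key=lambda s: (len(s), sorted(s)),
    )


class TestMinimalGeneKnockouts:
    def test_isozyme_reaction_needs_all_three_genes(self, pyrcore):
        result = bs.minimal_gene_knockouts(pyrcore, {"ADH"})
        assert [set(ks.genes) for ks in result] == [{"ADH1", "ADH3", "ADH5"}]
        assert result[0].side_effects == ()

    def test_shared_gene_reports_side_effect(self, pyrcore):
        # PDC1 also drives the acetoin condensation reaction
        result = bs.minimal_gene_knockouts(pyrcore, {"PDC"})
        assert [set(ks.genes) for ks in result] == [{"PDC1"}]
        assert result[0].side_effects == ("ACB",)

    def test_empty_target_set(self, pyrcore):
        result = bs.minimal_gene_knockouts(pyrcore, set())
        assert len(result) == 1
        assert result[0].genes == frozenset()
        assert result[0].side_effects == ()

    def test_always_on_reaction_is_not_gene_disableable(self, pyrcore):
        with pytest.raises(NotGeneDisableableError, match="RESP"):
            bs.minimal_gene_knockouts(pyrcore, {"RESP"})

    @pytest.mark.parametrize("targets", [{"ADH"}, {"GPD"}, {"PDC"}, {"ADH", "GPD"},
                                         {"BDH", "PDC"}, {"ADH", "BDH", "GPD"}])
    def test_agrees_with_exhaustive_subset_oracle(self, pyrcore, targets):
        expected = _brute_force_minimal_sets(pyrcore, targets)
        got = [ks.genes for ks in bs.minimal_gene_knockouts(pyrcore, targets)]
        assert got == expected


# ---------------------------------------------------------------------------
# Serialization round trips
# ---------------------------------------------------------------------------

def _random_models(n):
    return [
        bs.make_random_model(
            bs.RandomModelSpec(seed=seed, n_segments=2 + seed % 3,
                               n_cofactor_pairs=1 + seed % 2,
                               n_branch_products=2 + seed % 2)
        )
        for seed in range(n)
    ]


class TestRoundTrips:
    def test_json_round_trip_pyrcore(self, pyrcore, tmp_path):
        p = tmp_path / "m.json"
        bs.write_model_json(pyrcore, p)
        again = bs.read_model_json(p)
        assert model_to_dict(again) == model_to_dict(pyrcore)

    @pytest.mark.parametrize("dialect", ["fbc", "cobra-notes"])
    def test_sbml_round_trip_pyrcore(self, pyrcore, tmp_path, dialect):
        p = tmp_path / "m.xml"
        bs.write_sbml(pyrcore, p, dialect=dialect)
        again = bs.read_sbml(p)
        assert model_to_dict(again) == model_to_dict(pyrcore)
        # double round trip is stable
        p2 = tmp_path / "m2.xml"
        bs.write_sbml(again, p2, dialect=dialect)
        assert model_to_dict(bs.read_sbml(p2)) == model_to_dict(pyrcore)

    def test_round_trips_on_seeded_random_models(self, tmp_path):
        for i, model in enumerate(_random_models(10)):
            pj = tmp_path / f"r{i}.json"
            bs.write_model_json(model, pj)
            assert model_to_dict(bs.read_model_json(pj)) == model_to_dict(model)
            for dialect in ("fbc", "cobra-notes"):
                px = tmp_path / f"r{i}_{dialect}.xml"
                bs.write_sbml(model, px, dialect=dialect)
                assert model_to_dict(bs.read_sbml(px)) == model_to_dict(model)

    def test_empty_gprs_preserved(self, tmp_path):
        model = bs.MetabolicModel(
            id="nogpr",
            metabolites=[bs.Metabolite("a_c", "", "c"), bs.Metabolite("b_c", "", "c")],
            reactions=[
                bs.Reaction(id="EX_a", stoichiometry={"a_c": 1.0}, lower_bound=-5.0),
                bs.Reaction(id="R1", stoichiometry={"a_c": -1.0, "b_c": 1.0}),
                bs.Reaction(id="EX_b", stoichiometry={"b_c": -1.0}),
            ],
            genes=frozenset(),
            objective_id="EX_b",
        )
        p = tmp_path / "m.json"
        bs.write_model_json(model, p)
        again = bs.read_model_json(p)
        assert all(r.gpr is GPR_TRUE or r.gpr.is_always_on for r in again.reactions)

    def test_json_missing_reactions_key_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.json"
        doc = model_to_dict(bs.make_pyrcore())
        del doc["reactions"]
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="reactions"):
            bs.read_model_json(p)

    def test_sbml_reaction_without_bounds_rejected(self, pyrcore, tmp_path):
        p = tmp_path / "nobounds.xml"
        bs.write_sbml(pyrcore, p, dialect="cobra-notes")
        text = p.read_text()
        # strip the kinetic-law bound parameters from one reaction
        start = text.index('<reaction id="GPD"')
        kl_start = text.index("<kineticLaw>", start)
        kl_end = text.index("</kineticLaw>", kl_start) + len("</kineticLaw>")
        p.write_text(text[:kl_start] + text[kl_end:])
        with pytest.raises(SBMLError, match="GPD"):
            bs.read_sbml(p)

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<?xml version='1.0'?>\n<sbml><model></sbml>\n")
        with pytest.raises(SBMLError, match="line"):
            bs.read_sbml(p)


class TestModelValidation:
    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(bs.ModelValidationError, match="undeclared"):
            bs.MetabolicModel(
                id="bad",
                metabolites=[bs.Metabolite("a_c", "", "c")],
                reactions=[bs.Reaction(id="R", stoichiometry={"ghost_c": 1.0})],
                genes=frozenset(),
                objective_id="R",
            )

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            bs.Reaction(id="R", stoichiometry={"a": 1.0}, lower_bound=1.0, upper_bound=-1.0)

    def test_gpr_gene_must_be_declared(self):
        with pytest.raises(bs.ModelValidationError, match="absent"):
            bs.MetabolicModel(
                id="bad",
                metabolites=[bs.Metabolite("a_c", "", "c")],
                reactions=[
                    bs.Reaction(id="R", stoichiometry={"a_c": 1.0}, gpr=bs.parse_gpr("X1"))
                ],
                genes=frozenset(),
                objective_id="R",
            )
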