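"""Cocktail engine: group operators, formula parsing, unequivocal
classification against the packaged hierarchy."""

import numpy as np
import pytest

from vegclass.cocktail_engine import (
    And,
    DefinitionError,
    GroupCover,
    GroupPresence,
    GroupRegistry,
    Not,
    SpeciesCover,
    SpeciesGroup,
    classify,
    classify_table,
    max_single_cover,
    parse_definition,
    sociological_presence,
    total_cover,
)
from vegclass.releve_io import Releve, ReleveTable

from conftest import make_releve


@pytest.fixture(scope="module")
def tiny_groups():
    return GroupRegistry(
        [
            SpeciesGroup("G tc", "TC", ("Sp a", "Sp b", "Sp c")),
            SpeciesGroup("G sc", "SC", ("Sp a", "Sp b")),
            SpeciesGroup("G soc3", "SOC", ("Sp a", "Sp b", "Sp c")),
            SpeciesGroup("G soc4", "SOC", ("Sp a", "Sp b", "Sp c", "Sp d")),
        ]
    )


class TestGroupOperators:
    def test_total_cover_independence(self, tiny_groups):
        rel = make_releve({"Sp a": 50, "Sp b": 50})
        assert total_cover(rel, tiny_groups["G tc"]) == pytest.approx(75.0)

    def test_total_cover_absent_and_saturated(self, tiny_groups):
        assert total_cover(make_releve({"Other": 90}), tiny_groups["G tc"]) == 0.0
        rel = make_releve({"Sp a": 100, "Sp b": 30})
        assert total_cover(rel, tiny_groups["G tc"]) == pytest.approx(100.0)

    def test_total_cover_combines_layers(self, tiny_groups):
        rel = Releve("p1", {("Sp a", "herb"): 0.5, ("Sp a", "moss"): 0.5})
        assert total_cover(rel, tiny_groups["G tc"]) == pytest.approx(75.0)

    def test_max_single_cover(self, tiny_groups):
        rel = make_releve({"Sp a": 30, "Sp b": 10})
        assert max_single_cover(rel, tiny_groups["G sc"]) == pytest.approx(30.0)
        assert max_single_cover(make_releve({"Sp x": 55}), tiny_groups["G sc"]) == 0.0

    def test_total_cover_monotone_under_new_member(self, tiny_groups):
        base = make_releve({"Sp a": 40})
        more = make_releve({"Sp a": 40, "Sp c": 5})
        g = tiny_groups["G tc"]
        assert total_cover(more, g) >= total_cover(base, g)
        assert max_single_cover(more, tiny_groups["G sc"]) <= total_cover(more, g)

    @pytest.mark.parametrize(
        "present,n_members,expected",
        [(2, 3, True), (1, 3, False), (2, 4, True), (1, 4, False)],
    )
    def test_sociological_presence_default_half_rounded_up(
        self, tiny_groups, present, n_members, expected
    ):
        group = tiny_groups["G soc3" if n_members == 3 else "G soc4"]
        rel = make_releve({f"Sp {c}": 5 for c in "abcd"[:present]})
        assert sociological_presence(rel, group) is expected

    def test_min_members_override(self, tiny_groups):
        rel = make_releve({"Sp a": 5})
        assert sociological_presence(rel, tiny_groups["G soc3"], min_members=1)


class TestParser:
    def test_structure(self, tiny_groups):
        d = parse_definition("TC(G tc) > 25 AND SOC(G soc3)", tiny_groups)
        assert isinstance(d.root, And) and len(d.root.children) == 2
        assert isinstance(d.root.children[0], GroupCover)
        assert isinstance(d.root.children[1], GroupPresence)

    def test_not_over_species_cover(self, tiny_groups):
        d = parse_definition("NOT (COV(Sp a) >= 25)", tiny_groups)
        assert isinstance(d.root, Not)
        assert isinstance(d.root.child, SpeciesCover)
        assert d.root.child.op == ">="

    def test_unknown_group(self, tiny_groups):
        with pytest.raises(DefinitionError, match="unknown species group"):
            parse_definition("TC(Nonexistent) > 5", tiny_groups)

    def test_kind_mismatch(self, tiny_groups):
        with pytest.raises(DefinitionError, match="kind"):
            parse_definition("TC(G soc3) > 5", tiny_groups)

    def test_syntax_error_reports_position(self, tiny_groups):
        with pytest.raises(DefinitionError, match="position"):
            parse_definition("TC(G tc) > 25 AND AND", tiny_groups)

    def test_precedence_and_binds_tighter_than_or(self, tiny_groups):
        d = parse_definition(
            "SOC(G soc3) OR SOC(G soc4) AND TC(G tc) > 10", tiny_groups
        )
        # OR at the top, AND nested on the right
        from vegclass.cocktail_engine import Or

        assert isinstance(d.root, Or)
        assert isinstance(d.root.children[1], And)

    def test_evaluate_matches_hand_evaluation(self, tiny_groups):
        # hand evaluation: TC({a:20, b:10}) = 100*(1-0.8*0.9) = 28 > 25 (T);
        # SOC needs 2 of a,b,c -> T; NOT COV(d) > 5 -> T  => whole formula T
        d = parse_definition(
            "TC(G tc) > 25 AND SOC(G soc3) AND NOT COV(Sp d) > 5", tiny_groups
        )
        assert d.evaluate(make_releve({"Sp a": 20, "Sp b": 10}))
        assert not d.evaluate(make_releve({"Sp a": 20, "Sp b": 10, "Sp d": 10}))
        assert not d.evaluate(make_releve({"Sp a": 20}))  # SOC fails


class TestClassification:
    def test_single_association_assigns_whole_path(self, hierarchy):
        rel = make_releve(
            {"Eleocharis ovata": 40, "Carex bohemica": 30, "Juncus bufonius": 5}
        )
        res = classify(rel, hierarchy)
        assert res.association == "Polygono-Eleocharitetum ovatae"
        assert res.alliance == "Eleocharition soloniensis"
        assert res.klass == "Isoeto-Nanojuncetea"
        assert not res.conflict

    def test_multi_match_falls_back_to_alliance(self, hierarchy):
        # fires both the Centunculus and the Gypsophila sociological groups
        rel = make_releve(
            {
                "Anthoceros punctatus s. l.": 30,
                "Anagallis minima": 30,
                "Gypsophila muralis": 30,
                "Spergularia rubra": 30,
            }
        )
        res = classify(rel, hierarchy)
        assert res.association is None
        assert res.alliance == "Radiolion linoidis"
        assert len(res.conflict) == 2

    def test_nothing_matches(self, hierarchy):
        res = classify(make_releve({"Quercus robur": 80}), hierarchy)
        assert res.deepest is None and not res.conflict

    def test_class_only_fallback(self, hierarchy):
        # class members from different alliances: class total cover passes
        # but no alliance group does
        rel = make_releve(
            {"Eleocharis acicularis": 15, "Juncus bufonius": 10, "Myosurus minimus": 10}
        )
        res = classify(rel, hierarchy)
        assert res.klass == "Isoeto-Nanojuncetea"
        assert res.alliance is None and res.association is None

    def test_classification_invariant_on_random_releves(self, hierarchy):
        # hierarchy consistency: assigned ranks always form a root-anchored
        # path, on randomly assembled relevés
        rng = np.random.default_rng(0)
        pool = sorted(hierarchy.root.definition.root.group.members) + [
            "Alisma lanceolatum", "Bryum ruderale", "Stellaria alsine", "Quercus robur"
        ]
        for _ in range(500):
            k = rng.integers(1, 12)
            taxa = rng.choice(pool, size=k, replace=False)
            rel = make_releve(
                {t: c for t, c in zip(taxa, rng.uniform(0.1, 95, size=k))}
            )
            res = classify(rel, hierarchy)
            if res.association is not None:
                assert res.alliance is not None
            if res.alliance is not None:
                assert res.klass is not None
            if res.alliance and res.association:
                assert hierarchy.nodes[res.association].parent == res.alliance

    def test_classify_is_pure_and_order_invariant(self, hierarchy):
        species = {
            "Cyperus fuscus": 40, "Limosella aquatica": 20, "Juncus bufonius": 3
        }
        rel1 = make_releve(species)
        rel2 = Releve(
            "p1",
            dict(reversed(list(rel1.records.items()))),
        )
        assert classify(rel1, hierarchy) == classify(rel2, hierarchy)

    def test_classify_table_summary(self, hierarchy):
        rels = [
            make_releve({"Cyperus fuscus": 40, "Limosella aquatica": 20}, "a"),
            make_releve({"Quercus robur": 50}, "b"),
        ]
        results, summary = classify_table(ReleveTable(rels), hierarchy)
        assert len(results) == 2
        assert summary["by_rank"]["association"] == 1
        assert summary["by_rank"]["unassigned"] == 1
        assert summary["by_node"]["Isoeto-Nanojuncetea"] == 1

    def test_empty_table(self, hierarchy):
        results, summary = classify_table(ReleveTable([]), hierarchy)
        assert results == [] and summary["by_rank"]["association"] == 0
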