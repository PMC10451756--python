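"""Rule parsing, taxonomy matching, functional profiles, group comparison."""

import numpy as np
import pytest
from conftest import make_table

from _oracles import fisher_enumeration
from rhizocore import (
    assign_functions,
    bundled_rules,
    compare_groups,
    functional_profile,
    parse_lineage,
)
from rhizocore.function_rules import (
    FunctionalProfile,
    RuleParseError,
    clause_matches,
    parse_rules_text,
)


def lin(text, otu_id="x", dialect="plain_semicolon"):
    return parse_lineage(otu_id, text, dialect=dialect)


class TestParseRules:
    def test_minimal_two_line_rule(self):
        rules = parse_rules_text("nitrification\tmeta\n\t*Nitrospira*\n")
        assert len(rules) == 1
        assert rules[0].name == "nitrification"
        assert rules[0].clauses == ("*Nitrospira*",)

    def test_empty_file_yields_no_rules(self):
        assert parse_rules_text("") == []

    def test_comments_and_blanks_ignored(self):
        text = "# c\n\nfn\tmeta\n# inner\n\t*A*\n\t*B*\n"
        (rule,) = parse_rules_text(text)
        assert rule.clauses == ("*A*", "*B*")

    def test_include_resolves_to_clause_union(self):
        text = "base\t\n\t*A*\nwide\t\n\t*B*\n\tadd_group:base\n"
        rules = {r.name: r for r in parse_rules_text(text)}
        assert set(rules["wide"].clauses) == {"*A*", "*B*"}

    def test_include_of_undefined_function_errors(self):
        with pytest.raises(RuleParseError, match="undefined"):
            parse_rules_text("fn\t\n\tadd_group:ghost\n")

    def test_cyclic_include_errors(self):
        text = "a\t\n\tadd_group:b\nb\t\n\tadd_group:a\n"
        with pytest.raises(RuleParseError, match="cyclic"):
            parse_rules_text(text)

    def test_empty_rule_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no clauses"):
            rules = parse_rules_text("empty\t\nfull\t\n\t*A*\n")
        assert [r.name for r in rules] == ["full"]

    def test_duplicate_function_names_rejected(self):
        with pytest.raises(RuleParseError, match="duplicate"):
            parse_rules_text("fn\t\n\t*A*\nfn\t\n\t*B*\n")

    def test_clause_before_header_rejected(self):
        with pytest.raises(RuleParseError, match="before any"):
            parse_rules_text("\t*A*\n")

    def test_bundled_rule_set_parses(self):
        rules = bundled_rules()
        assert len(rules) >= 8
        names = {r.name for r in rules}
        assert {"nitrification", "nitrogen_fixation", "chemoheterotrophy"} <= names
        # methanol oxidation includes the methylotrophy clauses
        by_name = {r.name: r for r in rules}
        assert set(by_name["methylotrophy"].clauses) <= set(
            by_name["methanol_oxidation"].clauses
        )


class TestMatching:
    NITROSPIRA = "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae;Nitrospira"

    def test_wildcard_matches_rank_name(self):
        assert clause_matches("*Nitrospira*", lin(self.NITROSPIRA))

    def test_match_is_case_sensitive(self):
        assert not clause_matches("*nitrospira*", lin(self.NITROSPIRA))

    def test_full_path_pattern(self):
        assert clause_matches("Bacteria;Nitrospirae;*", lin(self.NITROSPIRA))
        assert not clause_matches("Bacteria;Firmicutes;*", lin(self.NITROSPIRA))

    def test_unanchored_pattern_requires_full_match(self):
        assert not clause_matches("Nitro", lin(self.NITROSPIRA))
        assert clause_matches("Nitrospira", lin(self.NITROSPIRA))

    def test_removing_wildcard_never_widens_match(self):
        lineages = [lin(self.NITROSPIRA), lin("Bacteria;Proteobacteria;;;;Sphingomonas")]
        for pattern in ("*Nitrospira*", "*Sphingomonas*", "*Bacteria*"):
            bare = pattern.strip("*")
            for L in lineages:
                if clause_matches(bare, L):
                    assert clause_matches(pattern, L)


class TestAssignFunctions:
    def test_nitrospira_assigned_to_nitrification(self):
        a = assign_functions({"x": lin(TestMatching.NITROSPIRA)}, bundled_rules())
        assert "nitrification" in a["x"]

    def test_empty_rule_list_assigns_nothing(self):
        assert assign_functions({"x": lin(TestMatching.NITROSPIRA)}, []) == {"x": set()}

    def test_bradyrhizobium_multifunctional(self):
        brad = lin(
            "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;"
            "Bradyrhizobiaceae;Bradyrhizobium"
        )
        a = assign_functions({"x": brad}, bundled_rules())["x"]
        assert {
            "nitrogen_fixation",
            "denitrification",
            "aromatic_compound_degradation",
        } <= a

    def test_unclassified_lineage_never_assigned(self):
        rules = parse_rules_text("catchall\t\n\t*\n")
        a = assign_functions({"x": lin("")}, rules)
        assert a["x"] == set()

    def test_adding_a_rule_grows_assignments_monotonically(self):
        lineages = {
            "a": lin(TestMatching.NITROSPIRA),
            "b": lin("Bacteria;Proteobacteria;;;;Sphingomonas"),
        }
        rules = bundled_rules()
        before = assign_functions(lineages, rules[:-1])
        after = assign_functions(lineages, rules)
        for otu in lineages:
            assert before[otu] <= after[otu]


class TestFunctionalProfile:
    def _table(self):
        # 4 OTUs, W group: OTU4 undetected in W
        return make_table(
            [[0.3, 0.3], [0.3, 0.3], [0.4, 0.4], [0.0, 0.0]],
            mode="proportion",
            sample_ids=["W1", "W2"],
            groups={"W1": "W", "W2": "W"},
        )

    def test_pct_of_detected_otus(self):
        t = self._table()
        prof = functional_profile(
            t, "W", {"OTU1": {"fermentation"}, "OTU2": set(), "OTU3": set()}
        )
        assert prof.total_otus == 3
        assert prof.pct("fermentation") == pytest.approx(100.0 / 3)

    def test_undetected_otus_excluded_from_denominator_and_counts(self):
        t = self._table()
        prof = functional_profile(t, "W", {"OTU4": {"fermentation"}})
        assert prof.total_otus == 3
        assert prof.n_assigned("fermentation") == 0

    def test_functions_not_mutually_exclusive(self):
        t = self._table()
        prof = functional_profile(
            t, "W", {"OTU1": {"fermentation", "ureolysis"}}, functions=None
        )
        assert prof.n_assigned("fermentation") == 1
        assert prof.n_assigned("ureolysis") == 1

    def test_profile_invariant_to_abundance_values(self):
        asg = {"OTU1": {"fermentation"}, "OTU2": set(), "OTU3": set()}
        a = functional_profile(self._table(), "W", asg)
        other = make_table(
            [[0.01, 0.98], [0.01, 0.01], [0.98, 0.01], [0.0, 0.0]],
            mode="proportion",
            sample_ids=["W1", "W2"],
            groups={"W1": "W", "W2": "W"},
        )
        b = functional_profile(other, "W", asg)
        assert a.per_function == b.per_function

    def test_no_detected_otus_errors(self):
        t = make_table(
            [[0.0, 1.0], [1.0, 0.0]],
            mode="proportion",
            sample_ids=["W1", "L1"],
            groups={"W1": "W", "L1": "L"},
        )
        t.data["W1"] = [0.0, 0.0]
        with pytest.raises(ValueError, match="no OTUs detected"):
            functional_profile(t, "W", {})


class TestCompareGroups:
    def _profiles(self, n_a, total_a, n_b, total_b, fn="fermentation"):
        a = FunctionalProfile("W", total_a, {fn: (n_a, 100 * n_a / total_a)})
        b = FunctionalProfile("L", total_b, {fn: (n_b, 100 * n_b / total_b)})
        return a, b

    def test_identical_proportions_p_is_one(self):
        a, b = self._profiles(5, 10, 5, 10)
        assert compare_groups(a, b, "fermentation").p_value == pytest.approx(1.0)

    def test_extreme_difference_small_p(self):
        a, b = self._profiles(9, 10, 1, 10)
        c = compare_groups(a, b, "fermentation")
        assert c.p_value == pytest.approx(fisher_enumeration(9, 10, 1, 10), abs=1e-10)
        assert c.p_value < 0.005

    def test_most_extreme_table_matches_enumeration(self):
        a, b = self._profiles(0, 10, 10, 10)
        c = compare_groups(a, b, "fermentation")
        assert c.p_value == pytest.approx(fisher_enumeration(0, 10, 10, 10), abs=1e-10)

    def test_absent_function_counts_as_zero(self):
        a = FunctionalProfile("W", 10, {})
        b = FunctionalProfile("L", 10, {"fermentation": (5, 50.0)})
        c = compare_groups(a, b, "fermentation")
        assert c.n_a == 0 and c.n_b == 5

    def test_zero_total_rejected(self):
        a = FunctionalProfile("W", 0, {})
        b = FunctionalProfile("L", 10, {})
        with pytest.raises(ValueError, match="nonzero"):
            compare_groups(a, b, "fermentation")

    def test_ztest_option_agrees_in_direction(self):
        a, b = self._profiles(40, 100, 10, 100)
        fisher = compare_groups(a, b, "fermentation", test="fisher").p_value
        z = compare_groups(a, b, "fermentation", test="ztest").p_value
        assert fisher < 0.01 and z < 0.01

    @pytest.mark.parametrize("seed", range(20))
    def test_fisher_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        total_a, total_b = int(rng.integers(2, 26)), int(rng.integers(2, 26))
        n_a, n_b = int(rng.integers(0, total_a + 1)), int(rng.integers(0, total_b + 1))
        a, b = self._profiles(n_a, total_a, n_b, total_b)
        c = compare_groups(a, b, "fermentation")
        assert c.p_value == pytest.approx(
            fisher_enumeration(n_a, total_a, n_b, total_b), abs=1e-10
        )
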