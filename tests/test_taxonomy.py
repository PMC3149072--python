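"""Regex mini-syntax parsing, class matching, periodicity classes, and
proline backbone categories."""

import pytest

from protrp.taxonomy import (PatternSyntaxError, assign_classes,
                             backbone_category, classify_period,
                             load_class_definitions, match_class,
                             parse_class_def, periodicity_histogram)
from protrp.trdetect import detect_repeats

TP3A = "[TS]P{3,4}[VA]{1,2}[TS].P and not [HY]"


class TestParser:
    def test_tp3a_structure(self):
        d = parse_class_def(TP3A, name="tp3a")
        assert len(d.inclusion) == 6
        assert d.exclusion_residues == {"H", "Y"}
        kinds = [a.kind for a in d.inclusion]
        assert kinds == ["class", "literal", "class", "class", "any",
                         "literal"]
        assert (d.inclusion[1].min_rep, d.inclusion[1].max_rep) == (3, 4)

    def test_multi_motif_alternation(self):
        d = parse_class_def("[AP|ST]", name="x")
        assert d.inclusion[0].kind == "alt"
        assert d.inclusion[0].payload == ("AP", "ST")

    def test_negated_class(self):
        d = parse_class_def("[^P]P", name="x")
        assert d.inclusion[0].kind == "negclass"
        assert match_class("AP", d)
        assert not match_class("PP", d)

    @pytest.mark.parametrize("text", [
        "P{4,2}",        # inverted bounds
        "[TSP",          # unbalanced bracket
        "[]P",           # empty alternation
        "[A|]",          # empty alternation branch
        "P{a,b}",        # malformed repetition
        "",              # empty pattern
    ])
    def test_parse_errors(self, text):
        with pytest.raises(PatternSyntaxError):
            parse_class_def(text, name="bad")

    def test_error_carries_position(self):
        with pytest.raises(PatternSyntaxError) as err:
            parse_class_def("PP[TS", name="bad")
        assert err.value.position == 2

    def test_canonical_round_trip_is_fixed_point(self):
        for expr in (TP3A, "[AP|ST]", "P{2}[^AG].K", "[TS]P{3,4}A"):
            d = parse_class_def(expr, name="x")
            d2 = parse_class_def(d.canonical, name="x")
            assert d2.canonical == d.canonical

    def test_name_tab_expression_form(self):
        d = parse_class_def("tp3a\t" + TP3A)
        assert d.name == "tp3a"


class TestMatching:
    def setup_method(self):
        self.tp3a = parse_class_def(TP3A, name="tp3a")

    def test_published_reading_matches(self):
        assert match_class("TPPPVTAP", self.tp3a)

    def test_exclusion_vetoes_anywhere(self):
        assert not match_class("TPPPVTAPH", self.tp3a)
        assert not match_class("YTPPPVTAP", self.tp3a)

    def test_unrelated_motif_rejected(self):
        assert not match_class("GGGGG", self.tp3a)

    def test_rotation_invariance(self):
        s = "TPPPVTAP"
        for k in range(len(s)):
            assert match_class(s[k:] + s[:k], self.tp3a)

    def test_full_domain_mode_disables_rotation(self):
        s = "TAPTPPPV"  # a rotation; pattern only matches cyclically
        assert match_class(s, self.tp3a, rotate=True)
        assert not match_class(s, self.tp3a, rotate=False)


class TestAssignment:
    def test_empty_definitions_leave_all_unmatched(self):
        table = assign_classes(["PVPVK", "AVYK"], [])
        assert not table["matched"].any()
        assert len(table) == 2

    def test_single_match_recorded(self):
        defs = [parse_class_def("PVK", name="pvk")]
        table = assign_classes(["PVPVK", "GGGG"], defs)
        hit = table[table.matched]
        assert list(hit["tr_class"]) == ["pvk"]
        assert list(hit["index"]) == [0]

    def test_generator_motif_round_trip(self):
        # a domain planted from a family motif matches that family's
        # shipped class definition
        defs = {d.name: d for d in load_class_definitions()}
        doms = detect_repeats("SPPPPYVYK" * 3)
        assert doms and match_class(doms[0].consensus, defs["syn_ext"])

    def test_multi_class_hits_reported(self):
        defs = [parse_class_def("PV", name="a"),
                parse_class_def("VK", name="b")]
        table = assign_classes(["PVK"], defs)
        assert sorted(table["tr_class"]) == ["a", "b"]


class TestPeriodicity:
    @pytest.mark.parametrize("period,cls", [
        (10, "n_plus_1"), (16, "n_plus_1"), (12, "n"), (14, "n_minus_1"),
        (9, "n"), (1, "n_plus_1"), (2, "n_minus_1"), (3, "n"),
    ])
    def test_examples(self, period, cls):
        assert classify_period(period) == cls

    def test_classes_partition_positive_integers(self):
        for p in range(1, 101):
            assert classify_period(p) in ("n", "n_plus_1", "n_minus_1")
            assert sum(classify_period(p) == c
                       for c in ("n", "n_plus_1", "n_minus_1")) == 1

    def test_histogram_counts_and_fractions(self):
        doms = (detect_repeats("ASPPYKVEQT" * 3)          # period 10
                + detect_repeats("SPPPPYVYK" * 3))        # period 9
        hist, frac = periodicity_histogram(doms)
        assert hist[10] == 1 and hist[9] == 1
        assert frac["n_plus_1"] == pytest.approx(0.5)
        assert frac["n"] == pytest.approx(0.5)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_empty_input(self):
        hist, frac = periodicity_histogram([])
        assert hist.empty
        assert all(v == 0.0 for v in frac.values())


class TestBackbone:
    @pytest.mark.parametrize("consensus,category", [
        ("SPPPPVYK", "SPn"),
        ("TPPPTA", "TPn"),
        ("PVEKP", "interspersed_P1"),
        ("PPVEK", "regular_P2"),
        ("PPVEKPA", "interspersed_P2_P1"),
        ("PPVKPPPEK", "regular_P2_P3"),
        ("PPVKPPPEKPA", "interspersed_P2_P3_P1"),
        ("AVEK", "other"),
    ])
    def test_categories(self, consensus, category):
        assert backbone_category(consensus) == category

    def test_deterministic(self):
        assert backbone_category("SPPPPVYK") == \
            backbone_category("SPPPPVYK")
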