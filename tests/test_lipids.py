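"""Lipid quantification arithmetic and inventory summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhpdkit import (epimer_fraction, methylation_degree, normalize_inventory,
                     quantify_by_internal_standard, summarize_inventory)
from bhpdkit.structures import parse_code, reference_structures

positive_area = st.floats(min_value=1e-6, max_value=1e9,
                          allow_nan=False, allow_infinity=False)


class TestInternalStandard:
    def test_equal_areas_give_is_mass_over_biomass(self):
        # 150 uL of 0.205 mg/mL internal standard = 0.03075 mg
        conc = quantify_by_internal_standard(1000.0, 1000.0, 0.03075, 0.030)
        assert conc == pytest.approx(1.025)

    def test_zero_analyte_gives_zero(self):
        assert quantify_by_internal_standard(0.0, 500.0, 0.03075, 0.02) == 0.0

    def test_linearity(self):
        a = quantify_by_internal_standard(100.0, 400.0, 0.03075, 0.01)
        b = quantify_by_internal_standard(200.0, 400.0, 0.03075, 0.01)
        assert b == pytest.approx(2 * a)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            quantify_by_internal_standard(1.0, 0.0, 0.03075, 0.01)
        with pytest.raises(ValueError):
            quantify_by_internal_standard(1.0, 1.0, 0.03075, 0.0)


class TestRatios:
    @pytest.mark.parametrize("me,un,expected", [
        (5.1, 94.9, 5.1), (0.0, 7.0, 0.0), (3.0, 3.0, 50.0)])
    def test_methylation_degree(self, me, un, expected):
        assert methylation_degree(me, un) == pytest.approx(expected)

    @pytest.mark.parametrize("s,r,expected", [(79, 21, 79), (0, 5, 0), (2, 2, 50)])
    def test_epimer_fraction(self, s, r, expected):
        assert epimer_fraction(s, r) == pytest.approx(expected)

    def test_both_zero_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            methylation_degree(0, 0)
        with pytest.raises(ValueError):
            epimer_fraction(0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(positive_area, positive_area, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, c):
        assert methylation_degree(a, b) == pytest.approx(methylation_degree(a * c, b * c))
        assert epimer_fraction(a, b) == pytest.approx(epimer_fraction(a * c, b * c))


class TestInventory:
    def test_singleton_is_100_percent(self):
        inv = normalize_inventory([(parse_code("IIIc"), 42.0)])
        assert len(inv) == 1 and inv.entries[0][1] == 100.0

    def test_proportionality_and_zero_drop(self):
        raw = [(parse_code("IIa"), 1.0), (parse_code("IIf"), 1.0),
               (parse_code("IIi"), 2.0), (parse_code("Va"), 0.0)]
        inv = normalize_inventory(raw)
        assert [round(a) for _, a in inv.entries] == [25, 25, 50]

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_inventory([(parse_code("IIa"), 0.0)])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(positive_area, min_size=1, max_size=8))
    def test_normalization_sums_to_100(self, responses):
        codes = ["IIa", "IIf", "IIi", "Va", "Ia", "IIIc", "IVb", "IIc"]
        raw = [(parse_code(codes[i]), r) for i, r in enumerate(responses)]
        inv = normalize_inventory(raw)
        assert inv.total() == pytest.approx(100.0, rel=1e-9)


class TestSummary:
    def test_empty_inventory(self):
        from bhpdkit.lipids import LipidInventory
        s = summarize_inventory(LipidInventory("x", []))
        assert s.n_bhpds == 0 and s.pct_unsaturated == 0.0

    def test_unsaturated_share(self):
        inv = normalize_inventory([(parse_code("IIa-d6"), 60.0), (parse_code("IIa"), 40.0)])
        s = summarize_inventory(inv)
        assert s.pct_unsaturated == pytest.approx(60.0)

    def test_known_class_mixture_matches_bookkeeping(self):
        # planted: 30% pentol-or-hexol based, 20% nucleoside, 10% unsaturated
        raw = [(parse_code("Ia"), 20.0), (parse_code("IIa"), 40.0),
               (parse_code("IIf"), 15.0), (parse_code("IIIe"), 15.0),
               (parse_code("IIa-d6"), 10.0)]
        s = summarize_inventory(normalize_inventory(raw))
        assert s.n_bhpds == 5
        assert s.pct_pentol_plus_hexol == pytest.approx(30.0)
        assert s.pct_by_group["nucleoside"] == pytest.approx(20.0)
        assert s.pct_unsaturated == pytest.approx(10.0)
        assert sum(s.pct_by_group.values()) == pytest.approx(100.0, abs=0.1)

    def test_fixture_inventory_single_ce(self):
        from bhpdkit import load_fixture
        inv_tab = load_fixture("inventory_F3")
        rows = inv_tab.frame[inv_tab.frame["species"] == "Rhizomicrobium palustre"]
        raw = [(parse_code(r["structure_code"]), float(r["rel_abundance_pct"]))
               for _, r in rows.iterrows()]
        inv = normalize_inventory(raw, "Rhizomicrobium palustre")
        assert len(inv) == 1 and inv.entries[0][1] == 100.0
        assert inv.entries[0][0].group == "ce"


def test_all_63_reference_structures_construct():
    roster = reference_structures()
    assert len(roster) == 63
    groups = {s.group for s in roster.values()}
    assert groups == {"nucleoside", "polyol", "ce", "carbamoyl", "amino"}
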