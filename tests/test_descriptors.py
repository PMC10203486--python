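"""Molecular indices, phenolic classification and weighted summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenolstress.descriptors import (abundance_diversity, aimod, dbe,
                                      dbe_standard, elemental_ratios,
                                      is_phenolic, nosc, summarize_phenolics,
                                      weighted_mean)
from phenolstress.formulas import AssignedPeak, Formula, parse_formula

formulas_with_carbon = st.builds(
    Formula, c=st.integers(1, 50), h=st.integers(0, 100),
    n=st.integers(0, 2), o=st.integers(0, 30), s=st.integers(0, 2))


class TestElementalRatios:
    def test_catechin(self, catechin):
        oc, hc, nc, sc = elemental_ratios(catechin)
        assert (oc, nc, sc) == (0.4, 0.0, 0.0)
        assert hc == pytest.approx(14 / 15)

    def test_methane_like(self):
        assert elemental_ratios(Formula(c=1, h=4))[1] == 4.0

    def test_symmetric_formula(self):
        oc, hc, nc, sc = elemental_ratios(parse_formula("C2H2N2O2S2"))
        assert (oc, hc, nc, sc) == (1.0, 1.0, 1.0, 1.0)

    def test_carbon_free_raises(self):
        with pytest.raises(ValueError):
            elemental_ratios(Formula(h=2, o=1))


class TestDBE:
    @pytest.mark.parametrize("hill,expected", [
        ("C15H14O6", 3.0),     # 1+15-6-0-7
        ("CH2", 1.0),
        ("C6H6O6", -2.0),      # negative permitted under this convention
    ])
    def test_heteroatom_subtracting_convention(self, hill, expected):
        assert dbe(parse_formula(hill)) == expected

    def test_differs_from_standard_dbe(self, catechin):
        assert dbe_standard(catechin) == 9.0   # 1+15-7
        assert dbe(catechin) == 3.0

    def test_standard_dbe_of_hydrocarbon(self):
        assert dbe_standard(parse_formula("C6H6")) == 4.0


class TestAImod:
    def test_catechin_is_half(self, catechin):
        assert aimod(catechin) == pytest.approx(0.5)

    def test_benzene(self):
        assert aimod(parse_formula("C6H6")) == pytest.approx(2 / 3)

    def test_nonpositive_denominator_convention(self):
        # C1H0O4: denominator 1 - 2 = -1 <= 0 -> 0 by convention
        assert aimod(Formula(c=1, o=4)) == 0.0

    def test_negative_numerator_convention(self):
        assert aimod(parse_formula("C2H8O2")) == 0.0

    @given(formulas_with_carbon)
    @settings(max_examples=1000, deadline=None)
    def test_matches_one_line_oracle(self, f):
        num = 1 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.h)
        den = f.c - 0.5 * f.o - f.n - f.s
        expected = num / den if den > 0 and num >= 0 else 0.0
        assert aimod(f) == pytest.approx(expected)


class TestNOSC:
    def test_fully_oxidized_limit(self):
        assert nosc(Formula(c=1, o=2)) == 4.0

    def test_fully_reduced_limit(self):
        assert nosc(Formula(c=1, h=4)) == -4.0

    def test_catechin(self, catechin):
        assert nosc(catechin) == pytest.approx(4 - 62 / 15)


class TestIsPhenolic:
    def test_catechin_is_phenolic(self, catechin):
        assert is_phenolic(catechin)

    def test_boundaries_are_strict(self):
        # H/C exactly 0.6 and exactly 1.5 both fail
        assert not is_phenolic(Formula(c=10, h=6, o=4))
        assert not is_phenolic(Formula(c=10, h=15, o=4))

    def test_oxygen_rich_rejected(self):
        assert not is_phenolic(Formula(c=10, h=10, o=9))   # O/C = 0.9

    def test_aromaticity_limit(self):
        # graphite-like: high AImod despite ratios in window
        f = Formula(c=20, h=13, o=7)
        assert (0.6 < f.h / f.c < 1.5) and (0.3 < f.o / f.c < 0.85)
        assert is_phenolic(f) == (aimod(f) < 0.67)

    @given(formulas_with_carbon)
    @settings(max_examples=300, deadline=None)
    def test_depends_only_on_ratios_and_aimod(self, f):
        expected = (0.6 < f.h / f.c < 1.5 and 0.3 < f.o / f.c < 0.85
                    and aimod(f) < 0.67)
        assert is_phenolic(f) == expected


class TestAbundanceDiversity:
    def test_single_formula_is_zero(self):
        assert abundance_diversity([42.0]).da == 0.0

    def test_four_equal_intensities(self):
        assert abundance_diversity([5, 5, 5, 5]).da == pytest.approx(0.75)

    def test_three_to_one(self):
        assert abundance_diversity([3, 1]).da == pytest.approx(0.375)

    def test_bounded_by_equal_abundance_maximum(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.lognormal(0, 1, rng.integers(2, 40))
            d = abundance_diversity(x)
            assert 0 <= d.da <= 1 - 1 / d.n_formulas + 1e-12

    def test_scale_invariance(self):
        x = [3.0, 1.0, 7.5, 0.2]
        assert abundance_diversity(x).da == pytest.approx(
            abundance_diversity([v * 1e6 for v in x]).da)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            abundance_diversity([0.0, 0.0])


class TestWeightedMean:
    def test_equal_weights_is_mean(self):
        assert weighted_mean([1, 2, 3], [5, 5, 5]) == pytest.approx(2.0)

    def test_zero_weight_ignored(self):
        assert weighted_mean([10, 99], [1, 0]) == 10.0

    def test_hand_example(self):
        assert weighted_mean([300, 500], [1, 3]) == pytest.approx(450.0)

    def test_zero_total_weight_raises(self):
        with pytest.raises(ValueError):
            weighted_mean([1, 2], [0, 0])


def _assigned(mz, intensity, hill):
    return AssignedPeak(mz=mz, intensity=intensity, formula=parse_formula(hill))


class TestSummarizePhenolics:
    def test_all_phenolic_gives_100_percent(self):
        peaks = [_assigned(289.07, 10, "C15H14O6"),
                 _assigned(300.06, 20, "C15H12O7")]
        s = summarize_phenolics(peaks)
        assert s.rel_intensity_pct == pytest.approx(100.0)
        assert s.n_phenolics == 2

    def test_known_intensity_fraction(self):
        peaks = [_assigned(289.07, 25, "C15H14O6"),   # phenolic
                 _assigned(255.23, 75, "C16H32O2")]   # palmitic acid: not
        s = summarize_phenolics(peaks)
        assert s.rel_intensity_pct == pytest.approx(25.0)

    def test_weighted_average_mz(self):
        peaks = [_assigned(300.0, 1, "C15H14O6"),
                 _assigned(400.0, 3, "C17H18O8")]
        assert summarize_phenolics(peaks).mz_wa == pytest.approx(375.0)

    def test_da_pools_peaks_sharing_a_formula(self):
        peaks = [_assigned(289.0718, 3, "C15H14O6"),
                 _assigned(289.0719, 1, "C15H14O6"),
                 _assigned(303.05, 4, "C15H12O7")]
        s = summarize_phenolics(peaks)
        assert s.n_phenolics == 2
        assert s.da.da == pytest.approx(0.5)     # equal 4/4 split

    def test_identical_formulas_weighted_index_equals_single(self, catechin):
        peaks = [_assigned(289.07, w, "C15H14O6") for w in (1, 5, 9)]
        s = summarize_phenolics(peaks)
        assert s.weighted.aimod == pytest.approx(0.5)
        assert s.weighted.dbe == pytest.approx(3.0)

    def test_no_phenolics_is_not_a_crash(self):
        s = summarize_phenolics([_assigned(255.23, 75, "C16H32O2")])
        assert s.n_phenolics == 0
        assert s.rel_intensity_pct == 0.0
        assert math.isnan(s.mz_wa)

    def test_scale_invariance(self):
        peaks = [_assigned(289.07, 2, "C15H14O6"),
                 _assigned(255.23, 6, "C16H32O2"),
                 _assigned(400.1, 1, "C17H18O8")]
        scaled = [AssignedPeak(mz=p.mz, intensity=p.intensity * 1e3,
                               formula=p.formula) for p in peaks]
        a, b = summarize_phenolics(peaks), summarize_phenolics(scaled)
        assert a.rel_intensity_pct == pytest.approx(b.rel_intensity_pct)
        assert a.mz_wa == pytest.approx(b.mz_wa)
        assert a.da.da == pytest.approx(b.da.da)
        assert a.weighted.oc == pytest.approx(b.weighted.oc)
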