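import math

import numpy as np
import pytest
from scipy import stats

from lohtime import (
    CnSegment,
    LohExtent,
    LohState,
    assign_mutant_allele,
    classify_locus,
    expected_vaf,
    state_from_copy_numbers,
    vaf_shift_test,
)

CHR17 = 81_195_210
TP53 = ("17", 7_565_096, 7_590_856)


def expected_state(major, minor):
    """Spec table re-derived independently of the implementation."""
    if minor == 0:
        return LohState.LOH_LOSS if major <= 1 else (
            LohState.CN_LOH if major == 2 else LohState.CG_LOH
        )
    return LohState.GAIN_NO_LOH if major >= 2 else LohState.NO_LOH


class TestStateTable:
    def test_exhaustive_enumeration_0_to_8(self):
        for major in range(9):
            for minor in range(major + 1):
                assert state_from_copy_numbers(major, minor) == expected_state(major, minor)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            state_from_copy_numbers(1, 2)


class TestClassifyLocus:
    def test_whole_chromosome_cn_loh(self):
        segs = [CnSegment("17", 0, CHR17, 2, 0)]
        call = classify_locus(segs, TP53, CHR17)
        assert call.state == LohState.CN_LOH
        assert call.extent == LohExtent.WHOLE_CHROMOSOME
        assert (call.mutant_copies, call.wildtype_copies) == (2, 0)

    def test_segmental_copy_gain_loh(self):
        segs = [
            CnSegment("17", 0, 5_000_000, 1, 1),
            CnSegment("17", 5_000_000, 15_000_000, 3, 0),  # 10 Mb window
            CnSegment("17", 15_000_000, CHR17, 1, 1),
        ]
        call = classify_locus(segs, TP53, CHR17)
        assert call.state == LohState.CG_LOH
        assert call.extent == LohExtent.SEGMENTAL
        assert call.mutant_copies == 3

    def test_diploid_heterozygous_is_no_loh(self):
        call = classify_locus([CnSegment("17", 0, CHR17, 1, 1)], TP53, CHR17)
        assert call.state == LohState.NO_LOH
        assert call.extent == LohExtent.NA

    @pytest.mark.parametrize("frac,expected", [
        (0.96, LohExtent.WHOLE_CHROMOSOME),
        (0.94, LohExtent.SEGMENTAL),
    ])
    def test_whole_chromosome_threshold_both_sides(self, frac, expected):
        span = int(CHR17 * frac)
        segs = [
            CnSegment("17", 0, span, 2, 0),
            CnSegment("17", span, CHR17, 1, 1),
        ]
        assert classify_locus(segs, TP53, CHR17).extent == expected

    def test_uniform_state_run_spans_abutting_segments(self):
        half = CHR17 // 2
        segs = [
            CnSegment("17", 0, half, 2, 0),
            CnSegment("17", half, CHR17, 2, 0),
        ]
        assert classify_locus(segs, TP53, CHR17).extent == LohExtent.WHOLE_CHROMOSOME

    def test_no_covering_segment_is_fatal(self):
        with pytest.raises(ValueError, match="no copy-number segment"):
            classify_locus([CnSegment("17", 50_000_000, CHR17, 2, 0)], TP53, CHR17)

    def test_subclonal_only_coverage_flagged_low_confidence(self):
        segs = [CnSegment("17", 0, CHR17, 2, 0, clonal_fraction=0.4)]
        assert classify_locus(segs, TP53, CHR17).low_confidence


class TestAssignMutantAllele:
    def test_pure_tumor_cn_loh_vaf_near_one_is_major(self):
        res = assign_mutant_allele(0.5, 39, 40, purity=1.0, major=2, minor=0)
        assert res.allele == "MAJOR"

    def test_two_population_accounting_at_half_purity(self):
        # rho=0.5, (2,0): mutant-on-major expected VAF = (2*0.5+0.5)/(0.5*2+1) = 0.75
        res = assign_mutant_allele(0.5, 30, 40, purity=0.5, major=2, minor=0)
        assert res.expected_vaf["MAJOR"] == pytest.approx(0.75)
        assert res.expected_vaf["MINOR"] == pytest.approx(0.25)
        assert res.allele == "MAJOR"

    def test_likelihood_enumeration_oracle_2_1(self):
        # observed VAF near the mutant-on-minor expectation for (2,1)
        purity, major, minor = 0.8, 2, 1
        p_major = expected_vaf(major, purity, 3, normal_mutant_copies=1)
        p_minor = expected_vaf(minor, purity, 3, normal_mutant_copies=1)
        alt, depth = 35, 100
        res = assign_mutant_allele(0.5, alt, depth, purity, major, minor)
        want = (
            "MAJOR"
            if stats.binom.logpmf(alt, depth, p_major) > stats.binom.logpmf(alt, depth, p_minor)
            else "MINOR"
        )
        assert res.allele == want == "MINOR"

    def test_balanced_state_is_a_tie(self):
        res = assign_mutant_allele(0.5, 20, 40, purity=0.8, major=2, minor=2)
        assert res.tie and res.allele == "TIE"

    def test_antisymmetry_under_hypothesis_swap(self):
        # calling with (major, minor) swapped flips MAJOR <-> MINOR
        for alt in (20, 35, 50, 65, 80):
            a = assign_mutant_allele(0.5, alt, 100, 0.7, 2, 1)
            b = assign_mutant_allele(0.5, alt, 100, 0.7, 2, 1)
            assert a.allele == b.allele  # determinism
            swapped = {"MAJOR": "MINOR", "MINOR": "MAJOR", "TIE": "TIE"}
            assert a.expected_vaf["MAJOR"] >= a.expected_vaf["MINOR"]
            if not a.tie:
                # swapping the likelihood table swaps the winning hypothesis
                assert swapped[a.allele] == (
                    "MAJOR" if a.loglik["MINOR"] > a.loglik["MAJOR"] else "MINOR"
                )


class TestVafShiftTest:
    def test_identical_tables_p1(self):
        assert vaf_shift_test(25, 50, 25, 50) == pytest.approx(1.0)

    def test_strong_shift_significant(self):
        assert vaf_shift_test(25, 50, 49, 50) < 1e-6

    def test_tiny_shift_not_significant(self):
        assert vaf_shift_test(25, 50, 26, 50) > 0.5

    def test_matches_hypergeometric_enumeration(self):
        # brute-force two-sided Fisher p for a small table
        germ_alt, germ_depth, tum_alt, tum_depth = 3, 10, 8, 10
        k_total, n1 = germ_alt + tum_alt, germ_depth
        pmf = [
            math.comb(n1, k) * math.comb(tum_depth, k_total - k)
            for k in range(max(0, k_total - tum_depth), min(n1, k_total) + 1)
        ]
        total = sum(pmf)
        p_obs = math.comb(n1, germ_alt) * math.comb(tum_depth, k_total - germ_alt)
        expected = sum(p for p in pmf if p <= p_obs * (1 + 1e-12)) / total
        assert vaf_shift_test(germ_alt, germ_depth, tum_alt, tum_depth) == pytest.approx(expected)

    def test_zero_depth_fatal(self):
        with pytest.raises(ValueError):
            vaf_shift_test(0, 0, 10, 20)
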