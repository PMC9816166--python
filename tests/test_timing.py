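import itertools
import math

import numpy as np
import pytest

from lohtime import (
    CnSegment,
    MultiplicityCall,
    SnvRecord,
    TimingResult,
    bootstrap_ci,
    chronological_bound,
    compare_timing_groups,
    correlate_age,
    count_pre_post,
    first_gain_time_over_locus,
    molecular_time,
    multiplicity_weights,
    time_gain,
)
from lohtime.timing import time_gain_mixture


def call(m, clonal=True):
    return MultiplicityCall(m=m, m_continuous=float(m), ccf=1.0 if clonal else 0.4,
                            clonal=clonal, posterior={str(m): 1.0})


def snv(pos, chrom="17"):
    return SnvRecord(chrom, pos, "C", "T", 20, 40, 0, 40, context="ACG")


SEG = CnSegment("17", 0, 81_195_210, 2, 0)


def lineage_simulation(pi_true, major, minor, n, rng):
    """Independent forward oracle: draw each mutation's lineage directly
    from the copy-time accounting, bypassing the package's weight helper."""
    # enumerate (copy, era) cells with their rates
    cells = []  # (multiplicity, rate)
    if (major, minor) == (2, 0):
        cells = [(2, pi_true), (1, 2 * (1 - pi_true))]
    elif (major, minor) == (2, 1):
        cells = [(2, pi_true), (1, pi_true), (1, 3 * (1 - pi_true))]
    elif (major, minor) == (2, 2):
        cells = [(2, 2 * pi_true), (1, 4 * (1 - pi_true))]
    rates = np.array([r for _, r in cells])
    ms = np.array([m for m, _ in cells])
    draws = rng.choice(len(cells), size=n, p=rates / rates.sum())
    picked = ms[draws]
    return int((picked >= 2).sum()), int((picked == 1).sum())


class TestCountPrePost:
    def test_all_m2(self):
        snvs = [snv(i + 1) for i in range(5)]
        assert count_pre_post(snvs, [call(2)] * 5, SEG) == (5, 0, 0)

    def test_mixed_definition(self):
        snvs = [snv(i + 1) for i in range(35)]
        calls = [call(2)] * 10 + [call(1)] * 20 + [call(1, clonal=False)] * 5
        assert count_pre_post(snvs, calls, SEG) == (10, 20, 5)

    def test_ungained_segment_fatal(self):
        seg = CnSegment("17", 0, 100, 1, 1)
        with pytest.raises(ValueError, match="not gained"):
            count_pre_post([snv(5)], [call(1)], seg)

    def test_clock_filter_restricts_counts(self):
        snvs = [snv(i + 1) for i in range(4)]
        calls = [call(2), call(2), call(1), call(1)]
        keep = {1, 3}
        n2, n1, _ = count_pre_post(snvs, calls, SEG, clock_filter=lambda r: r.pos in keep)
        assert (n2, n1) == (1, 1)

    def test_expected_ratio_matches_lineage_accounting(self):
        # simulator weights at pi=0.3 on (2,0): P(m=2) = 0.3/(0.3+1.4)
        w = multiplicity_weights(2, 0, 0.3)
        assert w[2] / (w[2] + w[1]) == pytest.approx(0.3 / (0.3 + 2 * 0.7))


class TestMolecularTime:
    @pytest.mark.parametrize("state", [(2, 0), (2, 1), (2, 2)])
    def test_no_pre_gain_mutations_give_time_zero(self, state):
        assert molecular_time(0, 100, *state) == 0.0

    def test_all_pre_gain_cnloh_gives_time_one(self):
        assert molecular_time(50, 0, 2, 0) == 1.0

    def test_reference_value_cnloh(self):
        assert molecular_time(30, 140, 2, 0) == pytest.approx(0.3)

    @pytest.mark.parametrize("state", [(2, 0), (2, 1), (2, 2)])
    @pytest.mark.parametrize("pi_true", [0.1, 0.5, 0.9])
    def test_estimator_inverts_forward_lineage_simulation(self, state, pi_true):
        rng = np.random.default_rng(hash((state, pi_true)) % 2**31)
        n2, n1 = lineage_simulation(pi_true, *state, n=200_000, rng=rng)
        assert molecular_time(n2, n1, *state) == pytest.approx(pi_true, abs=0.01)

    def test_monotone_in_n2(self):
        for state in [(2, 0), (2, 1), (2, 2)]:
            values = [molecular_time(n2, 50, *state) for n2 in range(0, 40)]
            assert all(b >= a for a, b in zip(values, values[1:]))

    def test_cap_at_one(self):
        # (2,1) closed form can exceed 1 when n1 is small
        assert molecular_time(50, 10, 2, 1) == 1.0

    def test_unsupported_state_errors(self):
        with pytest.raises(ValueError, match="no closed form"):
            molecular_time(10, 10, 3, 0)


class TestBootstrap:
    def test_degenerate_all_pre_gain_ci(self):
        lo, hi = bootstrap_ci(50, 0, 0, 2, 0, B=100, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_fixed_seed_reproducible(self):
        a = bootstrap_ci(30, 140, 5, 2, 0, B=200, seed=42)
        b = bootstrap_ci(30, 140, 5, 2, 0, B=200, seed=42)
        assert a == b

    def test_too_few_mutations_undefined(self):
        lo, hi = bootstrap_ci(1, 0, 0, 2, 0, B=10, seed=0)
        assert math.isnan(lo) and math.isnan(hi)

    def test_interval_brackets_point_estimate(self):
        lo, hi = bootstrap_ci(30, 140, 0, 2, 0, B=500, seed=3)
        pi = molecular_time(30, 140, 2, 0)
        assert lo <= pi <= hi


class TestTimeGain:
    def test_full_result_fields(self):
        snvs = [snv(i + 1) for i in range(60)]
        calls = [call(2)] * 15 + [call(1)] * 40 + [call(1, clonal=False)] * 5
        res = time_gain(snvs, calls, SEG, B=100, seed=7)
        assert isinstance(res, TimingResult)
        assert (res.n_pre, res.n_post, res.n_subclonal) == (15, 40, 5)
        assert res.pi == pytest.approx(molecular_time(15, 40, 2, 0))
        assert res.ci_low <= res.pi <= res.ci_high
        assert not res.low_confidence

    def test_low_confidence_flag_below_min_count(self):
        snvs = [snv(i + 1) for i in range(10)]
        res = time_gain(snvs, [call(2)] * 5 + [call(1)] * 5, SEG, B=50, seed=1)
        assert res.low_confidence


class TestTimeGainMixture:
    def test_recovers_planted_time_and_brackets_truth(self):
        from lohtime import simulate_segment_readcounts

        rng = np.random.default_rng(55)
        sim = simulate_segment_readcounts(
            rng, 2000, 2, 0, 0.4, purity=0.7, depth=60.0, subclonal_fraction=0.0
        )
        res = time_gain_mixture(sim["alt"], sim["depth"], 0.7, SEG, B=200, seed=8)
        assert res.pi == pytest.approx(0.4, abs=0.05)
        assert res.ci_low <= 0.4 <= res.ci_high

    def test_mask_restricts_to_subset(self):
        from lohtime import simulate_segment_readcounts

        rng = np.random.default_rng(56)
        sim = simulate_segment_readcounts(
            rng, 1000, 2, 0, 0.5, purity=0.7, depth=60.0, subclonal_fraction=0.0
        )
        mask = np.zeros(1000, bool)
        mask[:400] = True
        res = time_gain_mixture(sim["alt"], sim["depth"], 0.7, SEG, B=50, seed=9, mask=mask)
        assert res.n_pre + res.n_post + res.n_subclonal == pytest.approx(400, abs=1)


class TestFirstGain:
    def seg(self, start, end, major=2, minor=0):
        return CnSegment("17", start, end, major, minor)

    def result(self, pi):
        return TimingResult(pi=pi, n_pre=10, n_post=10, ci_low=pi, ci_high=pi,
                            cn_state=(2, 0), n_boot=10)

    LOCUS = ("17", 7_565_096, 7_590_856)

    def test_single_overlapping_gain(self):
        timed = [(self.seg(0, 20_000_000), self.result(0.4))]
        assert first_gain_time_over_locus(timed, self.LOCUS).pi == 0.4

    def test_earliest_of_two_overlapping_gains(self):
        timed = [
            (self.seg(0, 20_000_000), self.result(0.6)),
            (self.seg(7_000_000, 8_000_000, 2, 1), self.result(0.2)),
        ]
        assert first_gain_time_over_locus(timed, self.LOCUS).pi == 0.2

    def test_gains_elsewhere_only_is_null(self):
        timed = [(self.seg(40_000_000, 60_000_000), self.result(0.2))]
        assert first_gain_time_over_locus(timed, self.LOCUS) is None


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        g = [0.1, 0.2, 0.3, 0.4]
        assert compare_timing_groups(g, g) == pytest.approx(1.0)

    def test_complete_separation_3v3_exact(self):
        # 20 arrangements; the two extreme ones give two-sided p = 2/20
        p = compare_timing_groups([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert p == pytest.approx(0.1)

    def test_exact_enumeration_oracle_3v2(self):
        a, b = [0.1, 0.2, 0.5], [0.3, 0.4]
        # enumerate all C(5,2) rank placements of group b
        ranks = {0.1: 1, 0.2: 2, 0.3: 3, 0.4: 4, 0.5: 5}
        obs = ranks[0.3] + ranks[0.4]
        sums = [sum(c) for c in itertools.combinations(range(1, 6), 2)]
        mean = np.mean(sums)
        p_expected = sum(
            1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12
        ) / len(sums)
        assert compare_timing_groups(a, b) == pytest.approx(p_expected)

    def test_empty_group_fatal(self):
        with pytest.raises(ValueError):
            compare_timing_groups([], [0.1])


class TestAgeCorrelation:
    def test_perfect_linear(self):
        r, p = correlate_age([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_anticorrelation(self):
        r, _ = correlate_age([0.1, 0.2, 0.3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        r, p = correlate_age([0.5, 0.5, 0.5], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_null_simulation_r_small(self):
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(50):
            r, _ = correlate_age(rng.random(100), rng.random(100))
            rs.append(abs(r))
        assert np.mean(rs) < 0.15


class TestChronologicalBound:
    def test_no_pre_gain_clock_mutations_mean_early_event(self):
        assert chronological_bound(0, 50, 2, 0, age_at_dx=10.0) == 0.0

    def test_all_pre_gain_bound_equals_age(self):
        assert chronological_bound(30, 0, 2, 0, age_at_dx=12.0) == pytest.approx(12.0)

    def test_planted_fraction_scales_age(self):
        # gain at 20% of mutational history, age 10 -> ~2 years
        n_pre, n_post = 20, 160  # pi = 2*20/(40+160) = 0.2
        assert chronological_bound(n_pre, n_post, 2, 0, 10.0) == pytest.approx(2.0)

    def test_no_clock_mutations_is_null(self):
        assert chronological_bound(0, 0, 2, 0, 10.0) is None
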