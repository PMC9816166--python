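"""Molecular timing of copy-number gains from multiplicity-stratified counts.

A clonal mutation that arose before a gain is carried by every product of the
duplicated copy (multiplicity >= 2); one arising after sits on a single copy
(multiplicity 1). Under a constant per-copy mutation rate, the pre/post
counts (n2, n1) identify the molecular time pi in [0, 1] of the gain:

    (2,0)  pre-gain rate 1 copy (the surviving allele), post-gain 2 copies:
           E[n2] = C*pi, E[n1] = 2C(1-pi)      ->  pi = 2 n2 / (2 n2 + n1)
    (2,1)  one untouched copy accumulates m=1 mutations throughout:
           E[n2] = C*pi, E[n1] = C(3 - 2 pi)   ->  pi = 3 n2 / (2 n2 + n1)
    (2,2)  synchronous double gain from (1,1):
           E[n2] = 2C*pi, E[n1] = 4C(1-pi)     ->  pi = 2 n2 / (2 n2 + n1)

Copy-gain LOH states (major >= 3) are not timed by these closed forms.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import CnSegment, MultiplicityCall, SnvRecord, TimingResult

SUPPORTED_STATES = {(2, 0), (2, 1), (2, 2)}
DEFAULT_MIN_COUNT = 20
DEFAULT_N_BOOT = 200


def count_pre_post(
    snvs: Sequence[SnvRecord],
    multiplicity_calls: Sequence[MultiplicityCall],
    segment: Optional[CnSegment] = None,
    clock_filter: Optional[Callable[[SnvRecord], bool]] = None,
) -> Tuple[int, int, int]:
    """Count clonal pre-gain (m>=2), post-gain (m=1) and subclonal mutations.

    With ``clock_filter`` set, only mutations it accepts are counted.
    """
    if segment is not None and segment.major < 2:
        raise ValueError(
            f"segment ({segment.major},{segment.minor}) is not gained; cannot time"
        )
    if len(snvs) != len(multiplicity_calls):
        raise ValueError("snvs and multiplicity calls differ in length")
    n2 = n1 = n_sub = 0
    for snv, call in zip(snvs, multiplicity_calls):
        if clock_filter is not None and not clock_filter(snv):
            continue
        if not call.clonal:
            n_sub += 1
        elif call.m >= 2:
            n2 += 1
        else:
            n1 += 1
    return n2, n1, n_sub


def molecular_time(n2: int, n1: int, major: int, minor: int) -> float:
    """Closed-form molecular time of a gain; capped into [0, 1]."""
    if (major, minor) not in SUPPORTED_STATES:
        raise ValueError(
            f"no closed form for state ({major},{minor}); supported states are "
            f"{sorted(SUPPORTED_STATES)} — higher-gain states need a maximum-"
            "likelihood multi-event extension"
        )
    if n2 < 0 or n1 < 0:
        raise ValueError("negative counts")
    if n2 + n1 == 0:
        return 0.0
    numer = {(2, 0): 2.0, (2, 1): 3.0, (2, 2): 2.0}[(major, minor)] * n2
    pi = numer / (2.0 * n2 + n1)
    return min(pi, 1.0)


def bootstrap_ci(
    n2: int,
    n1: int,
    n_sub: int,
    major: int,
    minor: int,
    B: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for pi: resample the mutation set (with
    replacement) B times and recompute the closed form.

    Resampling N category-labelled mutations with replacement is done as a
    multinomial draw over the (pre, post, subclonal) counts. Returns
    (nan, nan) when fewer than two informative mutations exist.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if n2 + n1 < 2:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n_total = n2 + n1 + n_sub
    props = np.array([n2, n1, n_sub], dtype=float) / n_total
    draws = rng.multinomial(n_total, props, size=B)
    pis = np.empty(B)
    for i, (b2, b1, _) in enumerate(draws):
        pis[i] = molecular_time(int(b2), int(b1), major, minor)
    a = (1.0 - level) / 2.0
    return float(np.quantile(pis, a)), float(np.quantile(pis, 1.0 - a))


def time_gain(
    snvs: Sequence[SnvRecord],
    multiplicity_calls: Sequence[MultiplicityCall],
    segment: CnSegment,
    B: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    clock_filter: Optional[Callable[[SnvRecord], bool]] = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> TimingResult:
    """Full timing of one gained segment: counts, pi, bootstrap CI, flags."""
    n2, n1, n_sub = count_pre_post(snvs, multiplicity_calls, segment, clock_filter)
    raw_state = (segment.major, segment.minor)
    pi_raw = (
        {(2, 0): 2.0, (2, 1): 3.0, (2, 2): 2.0}[raw_state] * n2 / (2.0 * n2 + n1)
        if (n2 + n1) > 0 and raw_state in SUPPORTED_STATES
        else None
    )
    pi = molecular_time(n2, n1, segment.major, segment.minor)
    ci_low, ci_high = bootstrap_ci(n2, n1, n_sub, segment.major, segment.minor, B=B, seed=seed)
    if np.isnan(ci_low):
        ci_low = ci_high = pi
    return TimingResult(
        pi=pi,
        n_pre=n2,
        n_post=n1,
        ci_low=min(ci_low, pi),
        ci_high=max(ci_high, pi),
        cn_state=raw_state,
        n_boot=B,
        n_subclonal=n_sub,
        overflow=bool(pi_raw is not None and pi_raw > 1.0),
        low_confidence=(n2 + n1) < min_count,
    )


def time_gain_mixture(
    tumor_alt,
    tumor_depth,
    purity: float,
    segment: CnSegment,
    B: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    mask=None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> TimingResult:
    """Timing via the segment-level multiplicity mixture (soft counts).

    Fits the EM mixture over multiplicity components and evaluates the closed
    form on posterior-weighted (expected) counts — the consistent estimator
    when the binomial components overlap (hard argmax counts over-assign the
    minority multiplicity). The bootstrap resamples mutations with
    replacement, realised as multinomial weights on the responsibility rows.
    ``mask`` restricts the counted mutations (e.g. clock mutations only)
    without refitting the mixture.
    """
    from .multiplicity import fit_multiplicity_mixture

    alt = np.asarray(tumor_alt)
    depth = np.asarray(tumor_depth)
    if (segment.major, segment.minor) not in SUPPORTED_STATES:
        raise ValueError(
            f"no closed form for state ({segment.major},{segment.minor})"
        )
    mix = fit_multiplicity_mixture(alt, depth, purity, segment.cn_total, segment.major)
    r = mix.responsibilities
    if mask is not None:
        r = r[np.asarray(mask, bool)]
    n = r.shape[0]
    n2 = float(r[:, 1:mix.max_m].sum())
    n1 = float(r[:, 0].sum())
    n_sub = float(r[:, mix.max_m].sum())
    pi = molecular_time(n2, n1, segment.major, segment.minor)

    if n2 + n1 < 2 or n < 2:
        ci_low = ci_high = pi
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=B)  # (B, n)
        boot = counts @ r  # (B, K) soft category counts
        b2 = boot[:, 1:mix.max_m].sum(axis=1)
        b1 = boot[:, 0]
        factor = {(2, 0): 2.0, (2, 1): 3.0, (2, 2): 2.0}[(segment.major, segment.minor)]
        with np.errstate(invalid="ignore", divide="ignore"):
            pis = np.minimum(factor * b2 / (2.0 * b2 + b1), 1.0)
        pis = np.nan_to_num(pis, nan=0.0)
        ci_low = float(np.quantile(pis, 0.025))
        ci_high = float(np.quantile(pis, 0.975))

    factor = {(2, 0): 2.0, (2, 1): 3.0, (2, 2): 2.0}[(segment.major, segment.minor)]
    pi_raw = factor * n2 / (2.0 * n2 + n1) if (n2 + n1) > 0 else 0.0
    return TimingResult(
        pi=pi,
        n_pre=int(round(n2)),
        n_post=int(round(n1)),
        ci_low=min(ci_low, pi),
        ci_high=max(ci_high, pi),
        cn_state=(segment.major, segment.minor),
        n_boot=B,
        n_subclonal=int(round(n_sub)),
        overflow=bool(pi_raw > 1.0),
        low_confidence=(n2 + n1) < min_count,
    )


def first_gain_time_over_locus(
    timed_segments: Sequence[Tuple[CnSegment, TimingResult]],
    locus: Tuple[str, int, int],
) -> Optional[TimingResult]:
    """Earliest (smallest pi) gain among those overlapping the locus; None if
    no gained segment overlaps."""
    chrom, start, end = locus
    overlapping = [
        res
        for seg, res in timed_segments
        if seg.chrom == chrom and seg.start < end and start < seg.end and seg.major >= 2
    ]
    if not overlapping:
        return None
    return min(overlapping, key=lambda r: r.pi)


def compare_timing_groups(
    times_a: Sequence[float], times_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between two groups.

    Exact for small tie-free samples; normal approximation with tie
    correction otherwise.
    """
    a, b = np.asarray(times_a, float), np.asarray(times_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def correlate_age(
    times: Sequence[float], ages: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation (r, p) between molecular times and ages at
    diagnosis; (nan, nan) when either vector has zero variance."""
    t, y = np.asarray(times, float), np.asarray(ages, float)
    if len(t) != len(y):
        raise ValueError("length mismatch")
    if len(t) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(t) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(t, y)
    return float(r), float(p)


def chronological_bound(
    n_pre_clock: int,
    n_post_clock: int,
    major: int,
    minor: int,
    age_at_dx: float,
) -> Optional[float]:
    """Estimated age (years) at the gain, assuming clock mutations accrue
    linearly with age: age_gain = pi_clock * age_at_dx.

    This is a model-based bound, not a measurement; None when no clock
    mutations are available.
    """
    if age_at_dx <= 0:
        raise ValueError("age_at_dx must be > 0")
    if n_pre_clock + n_post_clock == 0:
        return None
    pi_clock = molecular_time(n_pre_clock, n_post_clock, major, minor)
    return pi_clock * age_at_dx
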