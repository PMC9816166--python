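"""Allele-specific LOH classification at a locus of interest.

Given clonal allele-specific copy number, a locus (e.g. *TP53*) is classified
by the (major, minor) state of the segment containing its midpoint:

    (1,1) -> NO_LOH          (0,0) or (1,0) -> LOH_LOSS (loss, no gain)
    (2,0) -> CN_LOH           (>=3,0) -> CG_LOH
    (major>=2, minor>=1) -> GAIN_NO_LOH (gain with wildtype retained)

The extent is WHOLE_CHROMOSOME when the uniform-state run of segments
covering the locus spans at least ``whole_chrom_frac`` of the chromosome.
Which physical allele (mutant vs wildtype) was gained is decided from the
tumor-vs-germline VAF of the germline variant under the purity-aware read
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .multiplicity import expected_vaf
from .types import CnSegment, LohCall, LohExtent, LohState

DEFAULT_WHOLE_CHROM_FRAC = 0.95
DEFAULT_CLONAL_FRACTION_MIN = 0.8

# TP53 locus, hg19 (chr17); supplied here as the conventional default — any
# locus interval can be passed instead.
TP53_HG19 = ("17", 7565096, 7590856)  # 0-based half-open


def state_from_copy_numbers(major: int, minor: int) -> LohState:
    """Total classification over all integer states 0 <= minor <= major."""
    if not (major >= minor >= 0):
        raise ValueError(f"invalid state ({major},{minor})")
    if minor == 0:
        if major <= 1:
            return LohState.LOH_LOSS
        if major == 2:
            return LohState.CN_LOH
        return LohState.CG_LOH
    if major >= 2:
        return LohState.GAIN_NO_LOH
    return LohState.NO_LOH


def classify_locus(
    segments: Sequence[CnSegment],
    locus_interval: Tuple[str, int, int],
    chrom_length: int,
    whole_chrom_frac: float = DEFAULT_WHOLE_CHROM_FRAC,
    min_clonal_fraction: float = DEFAULT_CLONAL_FRACTION_MIN,
    locus_name: str = "locus",
) -> LohCall:
    """Classify the LOH state and extent at a locus.

    The segment containing the locus midpoint determines the state; mutant
    copies default to the major allele (refine with
    :func:`assign_mutant_allele`).
    """
    chrom, start, end = locus_interval
    mid = (start + end) // 2
    on_chrom = sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)
    hits = [s for s in on_chrom if s.contains(mid)]
    if not hits:
        raise ValueError(f"no copy-number segment covers {chrom}:{mid + 1}")
    seg = hits[0]

    state = state_from_copy_numbers(seg.major, seg.minor)

    if state == LohState.NO_LOH:
        extent = LohExtent.NA
    else:
        # uniform-state run of segments around the hit
        idx = on_chrom.index(seg)
        run = [seg]
        for s in reversed(on_chrom[:idx]):
            if (s.major, s.minor) == (seg.major, seg.minor):
                run.insert(0, s)
            else:
                break
        for s in on_chrom[idx + 1:]:
            if (s.major, s.minor) == (seg.major, seg.minor):
                run.append(s)
            else:
                break
        run_span = sum(s.length for s in run)
        extent = (
            LohExtent.WHOLE_CHROMOSOME
            if run_span >= whole_chrom_frac * chrom_length
            else LohExtent.SEGMENTAL
        )

    if state == LohState.NO_LOH:
        mutant, wildtype = 1, 1
    elif state == LohState.GAIN_NO_LOH:
        mutant, wildtype = seg.major, seg.minor
    else:  # all minor=0 states: wildtype allele lost
        mutant, wildtype = seg.major, 0

    return LohCall(
        locus=locus_name,
        state=state,
        extent=extent,
        mutant_copies=mutant,
        wildtype_copies=wildtype,
        major=seg.major,
        minor=seg.minor,
        low_confidence=seg.clonal_fraction < min_clonal_fraction,
    )


@dataclass
class AlleleAssignment:
    allele: str  # "MAJOR", "MINOR" or "TIE"
    expected_vaf: Dict[str, float]
    loglik: Dict[str, float]
    tie: bool


def assign_mutant_allele(
    germline_vaf: float,
    tumor_alt: int,
    tumor_depth: int,
    purity: float,
    major: int,
    minor: int,
) -> AlleleAssignment:
    """Decide whether the germline (mutant) allele sits on the major or minor
    copy-number allele.

    For a heterozygous germline variant, normal cells contribute one mutant
    copy, so the expected tumor VAF with the mutant on an allele at copy
    number m is (m*rho + (1-rho)) / (rho*cn_tot + 2(1-rho)). The hypothesis
    with the higher binomial likelihood of the observed alt count wins.
    """
    if tumor_depth <= 0:
        raise ValueError("tumor_depth must be > 0")
    if not (0.25 <= germline_vaf <= 0.75):
        raise ValueError(
            f"germline VAF {germline_vaf} not consistent with a heterozygous variant"
        )
    cn_tot = major + minor
    exp = {
        "MAJOR": expected_vaf(major, purity, cn_tot, normal_mutant_copies=1),
        "MINOR": expected_vaf(minor, purity, cn_tot, normal_mutant_copies=1),
    }
    loglik = {
        k: float(stats.binom.logpmf(tumor_alt, tumor_depth, p)) for k, p in exp.items()
    }
    if major == minor or np.isclose(loglik["MAJOR"], loglik["MINOR"]):
        return AlleleAssignment("TIE", exp, loglik, tie=True)
    allele = "MAJOR" if loglik["MAJOR"] > loglik["MINOR"] else "MINOR"
    return AlleleAssignment(allele, exp, loglik, tie=False)


def vaf_shift_test(
    germ_alt: int, germ_depth: int, tum_alt: int, tum_depth: int
) -> float:
    """Two-sided Fisher's exact test for a tumor-vs-germline VAF shift."""
    if germ_depth <= 0 or tum_depth <= 0:
        raise ValueError("zero-depth sample")
    if germ_alt < 0 or tum_alt < 0 or germ_alt > germ_depth or tum_alt > tum_depth:
        raise ValueError("invalid counts")
    table = [[germ_alt, germ_depth - germ_alt], [tum_alt, tum_depth - tum_alt]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
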