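"""Telomere-content estimation from read sequences (TelSeq-style).

A read is telomeric when it carries at least ``min_repeats`` copies of the
TTAGGG motif (or its reverse complement CCCTAA). Mean telomere length is the
telomeric read mass divided by coverage in a GC-matched bin (telomeric
sequence is 50% GC, so GC ~48-52% reads set the local coverage scale),
split over the 46 chromosome ends of a diploid genome.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

from .contexts import revcomp
from .types import TelomereEstimate

TELOMERE_MOTIF = "TTAGGG"
DEFAULT_MIN_REPEATS = 12
DEFAULT_READ_LENGTH = 150
N_CHROMOSOME_ENDS = 46
GC_BIN = (0.48, 0.52)


def is_telomeric_read(
    read: str, repeat: str = TELOMERE_MOTIF, min_repeats: int = DEFAULT_MIN_REPEATS
) -> bool:
    """True when the read carries >= min_repeats non-overlapping motif copies
    on either strand (max over strands)."""
    read = read.upper()
    fwd = read.count(repeat)
    rev = read.count(revcomp(repeat))
    return max(fwd, rev) >= min_repeats


def count_telomeric_reads(
    reads: Iterable[str],
    repeat: str = TELOMERE_MOTIF,
    min_repeats: int = DEFAULT_MIN_REPEATS,
) -> int:
    return sum(is_telomeric_read(r, repeat, min_repeats) for r in reads)


def gc_fraction(read: str) -> float:
    read = read.upper()
    if not read:
        return 0.0
    return (read.count("G") + read.count("C")) / len(read)


def estimate_length(
    k_tel: int,
    n_gc: int,
    g_gc: float,
    n_ends: int = N_CHROMOSOME_ENDS,
    read_length: int = DEFAULT_READ_LENGTH,
) -> TelomereEstimate:
    """Mean telomere length per chromosome end, in kb.

    GC-matched coverage c = n_gc * read_length / g_gc; telomeric sequence
    mass k_tel * read_length / c is split over ``n_ends`` ends.
    """
    if n_gc <= 0:
        raise ValueError("n_gc must be > 0 (no GC-matched coverage)")
    if g_gc <= 0:
        raise ValueError("g_gc must be > 0")
    if k_tel < 0:
        raise ValueError("negative telomeric read count")
    coverage = n_gc * read_length / g_gc
    per_end_bp = (k_tel * read_length / coverage) / n_ends
    return TelomereEstimate(
        k_tel=k_tel, n_gc=n_gc, g_gc=g_gc, length_kb=per_end_bp / 1000.0
    )


def estimate_from_reads(
    reads: Sequence[str],
    g_gc: float,
    repeat: str = TELOMERE_MOTIF,
    min_repeats: int = DEFAULT_MIN_REPEATS,
    gc_bin: Tuple[float, float] = GC_BIN,
    n_ends: int = N_CHROMOSOME_ENDS,
    read_length: int = DEFAULT_READ_LENGTH,
) -> TelomereEstimate:
    """Classify reads and estimate telomere length in one pass.

    Reads passing the telomeric threshold are excluded from the GC bin so the
    estimate stays linear in planted telomere content.
    """
    k_tel = 0
    n_gc = 0
    lo, hi = gc_bin
    for read in reads:
        if is_telomeric_read(read, repeat, min_repeats):
            k_tel += 1
        elif lo <= gc_fraction(read) <= hi:
            n_gc += 1
    return estimate_length(k_tel, n_gc, g_gc, n_ends=n_ends, read_length=read_length)


def tn_ratio(tumor_kb: float, normal_kb: float) -> float:
    """Tumor/normal telomere-length ratio."""
    if normal_kb <= 0:
        raise ValueError("normal telomere length must be > 0")
    return tumor_kb / normal_kb
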