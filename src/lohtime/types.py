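"""Domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .contexts import CHANNELS, PYRIMIDINES


@dataclass
class SnvRecord:
    """One somatic single-nucleotide variant with tumor/normal allele depths.

    ``context`` is the pyrimidine-centred trinucleotide around the variant
    (e.g. ``"ACG"`` for an A[C>T]G call); ``ref``/``alt`` are stored on the
    same (pyrimidine) strand.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_alt: int
    tumor_depth: int
    normal_alt: int
    normal_depth: int
    context: Optional[str] = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(f"tumor counts invalid at {self.chrom}:{self.pos}")
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(f"normal counts invalid at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.context is not None and self.context[1] not in PYRIMIDINES:
            raise ValueError(
                f"context {self.context!r} not pyrimidine-centred at {self.chrom}:{self.pos}"
            )

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else float("nan")

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else float("nan")


@dataclass
class CnSegment:
    """Allele-specific copy-number segment; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if not (self.major >= self.minor >= 0):
            raise ValueError(
                f"major/minor invalid ({self.major},{self.minor}) at {self.chrom}:{self.start}"
            )

    @property
    def cn_total(self) -> int:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """pos is 0-based."""
        return self.start <= pos < self.end


@dataclass
class GermlineVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    germline_vaf: float


@dataclass
class SampleProfile:
    sample_id: str
    purity: float
    sex: str = "unknown"
    age_at_dx: Optional[float] = None
    germline_tp53: Optional[GermlineVariant] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0,1], got {self.purity}")


class LohState(str, Enum):
    NO_LOH = "NO_LOH"
    LOH_LOSS = "LOH_LOSS"  # loss without gain (1+0); representable, none observed in LFS tumors
    CN_LOH = "CN_LOH"  # copy-neutral LOH (2+0)
    CG_LOH = "CG_LOH"  # copy-gain LOH (>=3 + 0)
    GAIN_NO_LOH = "GAIN_NO_LOH"  # gain with wildtype retained (major>=2, minor>=1)


class LohExtent(str, Enum):
    SEGMENTAL = "SEGMENTAL"
    WHOLE_CHROMOSOME = "WHOLE_CHROMOSOME"
    NA = "NA"


@dataclass
class LohCall:
    locus: str
    state: LohState
    extent: LohExtent
    mutant_copies: int
    wildtype_copies: int
    major: int
    minor: int
    low_confidence: bool = False


@dataclass
class MultiplicityCall:
    """Per-mutation copy number (multiplicity), CCF and clonality."""

    m: int
    m_continuous: float
    ccf: float
    clonal: bool
    posterior: dict  # label ("1".."max_m", "subclonal") -> probability

    def __post_init__(self) -> None:
        total = sum(self.posterior.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"posterior sums to {total}, not 1")


@dataclass
class TimingResult:
    """Molecular time of a copy-number gain with bootstrap uncertainty."""

    pi: float
    n_pre: int  # clonal mutations at multiplicity >= 2 (before the gain)
    n_post: int  # clonal mutations at multiplicity 1 (after the gain)
    ci_low: float
    ci_high: float
    cn_state: tuple
    n_boot: int
    n_subclonal: int = 0
    overflow: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi out of [0,1]: {self.pi}")


@dataclass
class TelomereEstimate:
    k_tel: int
    n_gc: int
    g_gc: float
    length_kb: float

    def __post_init__(self) -> None:
        if self.length_kb < 0:
            raise ValueError("negative telomere length")


class SignatureCatalog:
    """A 96-context catalog: one probability vector per signature.

    ``probs`` is a (96, n_signatures) array; each column sums to 1.
    """

    def __init__(self, names, probs) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (96, len(names)):
            raise ValueError(f"catalog shape {probs.shape} != (96, {len(names)})")
        if np.any(probs < 0):
            raise ValueError("negative probability in catalog")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"signature columns must sum to 1, got {sums}")
        self.names = list(names)
        self.probs = probs

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.names.index(name)]

    channels = CHANNELS
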