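"""Synthetic tumor generator with known ground truth.

The generator reproduces the statistical structure the analysis assumes:

* a planted gain time ``pi_true`` on each gained segment fixes the lineage
  weights of mutation multiplicities (a clonal mutation predating the gain is
  carried at multiplicity 2; later ones at 1);
* trinucleotide contexts are drawn from a signature mixture (exposures x a
  96-channel catalog);
* sequencing coverage is Poisson, and the mutant read count binomial with
  success rate set by purity, local copy number and CCF.

Everything is deterministic under a fixed seed, and outputs round-trip
through the package's own readers (VCF with INFO/TNC, 1-based segment TSV,
truth JSON, FASTQ for telomere reads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contexts import CHANNELS
from .io import write_segments, write_snv_vcf
from .multiplicity import VAF_CAP_EPS
from .types import (
    CnSegment,
    GermlineVariant,
    SampleProfile,
    SignatureCatalog,
    SnvRecord,
)

CHR17_LENGTH = 81_195_210  # hg19 chromosome 17 span used by the defaults
TP53_START, TP53_END = 7_565_096, 7_590_856

_BASES = np.array(list("ACGT"))


def fixture_catalog() -> SignatureCatalog:
    """Built-in 3-signature catalog for download-free testing.

    SBS1-like: >=80% mass on CpG C>T channels (deamination clock);
    SBS5-like: flat over all 96 channels; APOBEC-like: mass on T[C>T/G]A/T.
    """
    cpg = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "C>T" and ch[6] == "G"]
    sbs1 = np.full(96, 0.15 / 92)
    sbs1[cpg] = 0.85 / len(cpg)

    sbs5 = np.full(96, 1.0 / 96)

    apobec_channels = [
        CHANNELS.index(label)
        for label in ("T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T")
    ]
    apobec = np.full(96, 0.10 / 92)
    apobec[apobec_channels] = 0.90 / 4
    return SignatureCatalog(
        ["SBS1", "SBS5", "APOBEC"], np.column_stack([sbs1, sbs5, apobec])
    )


@dataclass
class SimSegment:
    """Planted copy-number segment; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    pi_true: float = 0.0  # molecular time of the gain (ignored if major < 2)

    def as_cn_segment(self) -> CnSegment:
        return CnSegment(self.chrom, self.start, self.end, self.major, self.minor)


@dataclass
class TumorSimParams:
    """Study conditions for one simulated tumor.

    Defaults emulate the timed scenario: whole-chromosome copy-neutral LOH
    (2+0) of chr17 with the gain a quarter of the way through mutational
    time, purity 0.7 and 60x coverage.
    """

    sample_id: str = "SIM"
    purity: float = 0.7
    depth: float = 60.0
    n_mutations: int = 2000
    segments: List[SimSegment] = field(
        default_factory=lambda: [
            SimSegment("17", 0, CHR17_LENGTH, 2, 0, pi_true=0.25)
        ]
    )
    exposures: Dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.3, "SBS5": 0.5, "APOBEC": 0.2}
    )
    catalog: Optional[SignatureCatalog] = None
    subclonal_fraction: float = 0.1
    subclonal_ccf: float = 0.4
    age_at_dx: Optional[float] = None
    plant_germline: bool = True
    germline_depth: float = 40.0


def multiplicity_weights(major: int, minor: int, pi_true: float) -> Dict[int, float]:
    """Lineage weights of clonal multiplicities implied by a gain at time t.

    Pre-gain mutations on a to-be-duplicated copy end at multiplicity 2; all
    other (pre-gain untouched-copy and post-gain per-copy) mutations at 1.
    """
    if not (0.0 <= pi_true <= 1.0):
        raise ValueError("pi_true must be in [0,1]")
    t = pi_true
    if (major, minor) == (2, 0):
        return {2: t, 1: 2 * (1 - t)}
    if (major, minor) == (2, 1):
        return {2: t, 1: t + 3 * (1 - t)}
    if (major, minor) == (2, 2):
        return {2: 2 * t, 1: 4 * (1 - t)}
    if major < 2:  # no gain: every mutation sits on one copy
        return {1: float(major + minor)}
    raise ValueError(f"no lineage model for state ({major},{minor})")


def _channel_parts(idx: int) -> Tuple[str, str, str]:
    label = CHANNELS[idx]  # e.g. "A[C>T]G"
    return label[2], label[4], label[0] + label[2] + label[6]  # ref, alt, context


def simulate_segment_readcounts(
    rng: np.random.Generator,
    n: int,
    major: int,
    minor: int,
    pi_true: float,
    purity: float,
    depth: float,
    subclonal_fraction: float = 0.0,
    subclonal_ccf: float = 0.4,
) -> Dict[str, np.ndarray]:
    """Array backend: multiplicities, depths and alt counts for n mutations
    on one segment. Returns m_true, clonal, ccf, depth, alt arrays."""
    weights = multiplicity_weights(major, minor, pi_true)
    ms = np.array(sorted(weights), dtype=int)
    probs = np.array([weights[m] for m in ms], dtype=float)
    probs = probs / probs.sum()

    m_true = rng.choice(ms, size=n, p=probs)
    clonal = rng.random(n) >= subclonal_fraction
    m_true = np.where(clonal, m_true, 1)
    ccf = np.where(clonal, 1.0, subclonal_ccf)

    cn_tot = major + minor
    denom = purity * cn_tot + 2.0 * (1.0 - purity)
    p = np.minimum(m_true * ccf * purity / denom, 1.0 - VAF_CAP_EPS)

    depths = rng.poisson(depth, size=n)
    while np.any(depths == 0):  # keep every site sequenced
        zero = depths == 0
        depths[zero] = rng.poisson(depth, size=int(zero.sum()))
    alts = rng.binomial(depths, p)
    return {
        "m_true": m_true,
        "clonal": clonal,
        "ccf": ccf,
        "depth": depths,
        "alt": alts,
    }


@dataclass
class SimulatedTumor:
    params: TumorSimParams
    snvs: List[SnvRecord]
    segments: List[CnSegment]
    profile: SampleProfile
    truth: Dict

    def write(self, out_dir, prefix: Optional[str] = None) -> Dict[str, Path]:
        """Write VCF + segments TSV + truth JSON in the pipeline's dialects."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.params.sample_id
        paths = {
            "vcf": out_dir / f"{prefix}.snvs.vcf",
            "segments": out_dir / f"{prefix}.segments.tsv",
            "truth": out_dir / f"{prefix}.truth.json",
        }
        write_snv_vcf(self.snvs, paths["vcf"])
        write_segments(self.segments, paths["segments"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_tumor(params: TumorSimParams, seed: int) -> SimulatedTumor:
    """Generate one tumor: SNVs with read counts, segments, profile, truth."""
    rng = np.random.default_rng(seed)
    catalog = params.catalog or fixture_catalog()
    e = np.array([params.exposures.get(n, 0.0) for n in catalog.names], dtype=float)
    if np.any(e < 0) or not np.isclose(e.sum(), 1.0, atol=1e-9):
        raise ValueError(f"exposure vector must be nonnegative and sum to 1, got {e}")

    # mutations distributed over segments proportional to length x total CN
    seg_weights = np.array(
        [max(s.major + s.minor, 1) * (s.end - s.start) for s in params.segments],
        dtype=float,
    )
    seg_of = rng.choice(len(params.segments), size=params.n_mutations,
                        p=seg_weights / seg_weights.sum())

    # generating signature then channel, per mutation
    sig_of = rng.choice(catalog.n_signatures, size=params.n_mutations, p=e)
    channels = np.array(
        [rng.choice(96, p=catalog.probs[:, s]) for s in sig_of], dtype=int
    )

    snvs: List[SnvRecord] = []
    truth_rows = []
    for si, sim_seg in enumerate(params.segments):
        mask = seg_of == si
        n = int(mask.sum())
        if n == 0:
            continue
        arrays = simulate_segment_readcounts(
            rng, n, sim_seg.major, sim_seg.minor, sim_seg.pi_true,
            params.purity, params.depth,
            subclonal_fraction=params.subclonal_fraction,
            subclonal_ccf=params.subclonal_ccf,
        )
        positions = np.sort(rng.integers(sim_seg.start, sim_seg.end, size=n))
        normal_depths = rng.poisson(params.depth, size=n)
        idxs = np.where(mask)[0]
        for j in range(n):
            ref, alt_base, ctx = _channel_parts(int(channels[idxs[j]]))
            snvs.append(
                SnvRecord(
                    chrom=sim_seg.chrom,
                    pos=int(positions[j]) + 1,
                    ref=ref,
                    alt=alt_base,
                    tumor_alt=int(arrays["alt"][j]),
                    tumor_depth=int(arrays["depth"][j]),
                    normal_alt=0,
                    normal_depth=int(max(normal_depths[j], 1)),
                    context=ctx,
                )
            )
            truth_rows.append(
                {
                    "chrom": sim_seg.chrom,
                    "pos": int(positions[j]) + 1,
                    "segment": si,
                    "multiplicity": int(arrays["m_true"][j]),
                    "clonal": bool(arrays["clonal"][j]),
                    "ccf": float(arrays["ccf"][j]),
                    "signature": catalog.names[int(sig_of[idxs[j]])],
                    "channel": CHANNELS[int(channels[idxs[j]])],
                    "vaf_true": float(arrays["alt"][j] / arrays["depth"][j]),
                }
            )

    germline = None
    germline_truth = None
    if params.plant_germline:
        tp53_seg = next(
            (s for s in params.segments
             if s.chrom == "17" and s.start < TP53_END and TP53_START < s.end),
            params.segments[0],
        )
        pos = (TP53_START + TP53_END) // 2 + 1
        g_depth = max(int(rng.poisson(params.germline_depth)), 1)
        g_alt = int(rng.binomial(g_depth, 0.5))
        cn_tot = max(tp53_seg.major + tp53_seg.minor, 1)
        denom = params.purity * cn_tot + 2.0 * (1.0 - params.purity)
        # mutant allele planted on the major copy
        p_t = min(
            (tp53_seg.major * params.purity + (1.0 - params.purity)) / denom,
            1.0 - VAF_CAP_EPS,
        )
        t_depth = max(int(rng.poisson(params.depth)), 1)
        t_alt = int(rng.binomial(t_depth, p_t))
        germline = GermlineVariant(
            chrom="17", pos=pos, ref="C", alt="T",
            germline_vaf=g_alt / g_depth if g_depth else 0.5,
        )
        germline_truth = {
            "chrom": "17", "pos": pos, "ref": "C", "alt": "T",
            "germline_alt": g_alt, "germline_depth": g_depth,
            "tumor_alt": t_alt, "tumor_depth": t_depth,
            "mutant_allele": "MAJOR",
        }

    profile = SampleProfile(
        sample_id=params.sample_id,
        purity=params.purity,
        age_at_dx=params.age_at_dx,
        germline_tp53=germline,
    )
    truth = {
        "sample_id": params.sample_id,
        "seed": int(seed),
        "purity": params.purity,
        "depth": params.depth,
        "exposures": dict(params.exposures),
        "segments": [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "major": s.major, "minor": s.minor, "pi_true": s.pi_true,
            }
            for s in params.segments
        ],
        "mutations": truth_rows,
        "germline": germline_truth,
    }
    return SimulatedTumor(
        params=params,
        snvs=snvs,
        segments=[s.as_cn_segment() for s in params.segments],
        profile=profile,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# telomere read simulation


@dataclass
class TelomereSimParams:
    n_background: int = 2000  # reads emitted into the GC-matched bin
    telomeric_fraction: float = 0.01  # telomeric reads per background read
    read_length: int = 150
    noise_mismatches: int = 0  # random single-base changes per telomeric read
    g_gc: float = 1.0e6  # genome span the GC bin represents (bp)


def _telomeric_read(rng: np.random.Generator, length: int, mismatches: int) -> str:
    offset = int(rng.integers(0, 6))
    seq = ("TTAGGG" * (length // 6 + 2))[offset : offset + length]
    if mismatches:
        seq = list(seq)
        for pos in rng.choice(length, size=mismatches, replace=False):
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[int(rng.integers(0, 3))]
        seq = "".join(seq)
    if rng.random() < 0.5:
        from .contexts import revcomp

        seq = revcomp(seq)
    return seq


def _gc_bin_read(rng: np.random.Generator, length: int) -> str:
    # exactly 50% GC so the read falls in the GC-matched coverage bin
    half = length // 2
    gc = rng.choice(["G", "C"], size=half)
    at = rng.choice(["A", "T"], size=length - half)
    seq = np.concatenate([gc, at])
    rng.shuffle(seq)
    return "".join(seq)


def simulate_telomere_reads(
    params: TelomereSimParams, seed: int
) -> List[str]:
    """Reads for one sample: GC-bin background plus planted telomeric reads."""
    rng = np.random.default_rng(seed)
    n_tel = int(round(params.n_background * params.telomeric_fraction))
    reads = [_gc_bin_read(rng, params.read_length) for _ in range(params.n_background)]
    reads += [
        _telomeric_read(rng, params.read_length, params.noise_mismatches)
        for _ in range(n_tel)
    ]
    return reads


def write_fastq(reads: Sequence[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> List[str]:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip())
    return reads
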