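"""Readers and writers for the formats the pipeline touches.

On-disk conventions: VCF and segment TSV coordinates are 1-based (segments
1-based inclusive); everything in memory is 0-based half-open except
``SnvRecord.pos`` which keeps the familiar 1-based VCF position. Trinucleotide
contexts travel in the VCF ``INFO/TNC`` tag so that no reference genome is
needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .contexts import CHANNELS, PYRIMIDINES, revcomp, _COMPLEMENT
from .types import CnSegment, SignatureCatalog, SnvRecord

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chrom", "start", "end", "major", "minor", "clonal_fraction"]


@dataclass
class LoadedSnvs:
    """SNV records plus bookkeeping from a VCF load."""

    records: List[SnvRecord]
    n_indels_skipped: int = 0
    n_multiallelic_split: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _normalize_record(ref: str, alt: str, context) -> tuple:
    """Fold ref/alt/context onto the pyrimidine strand at load time."""
    if ref in PYRIMIDINES:
        return ref, alt, context
    return (
        _COMPLEMENT[ref],
        _COMPLEMENT[alt],
        revcomp(context) if context is not None else None,
    )


def load_snvs(vcf_path, tumor_sample: str, normal_sample: str) -> LoadedSnvs:
    """Read biallelic somatic SNVs from a VCF with FORMAT/AD depths.

    Multiallelic sites are split into one record per ALT; indels are skipped
    and counted. Raises ``ValueError`` if a sample name cannot be resolved or
    a record lacks allele depths.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
    t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)

    records: List[SnvRecord] = []
    n_indels = 0
    n_split = 0
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(
                f"missing FORMAT/AD at {variant.CHROM}:{variant.POS}"
            )
        context = variant.INFO.get("TNC")
        alts = variant.ALT
        if len(alts) > 1:
            n_split += len(alts) - 1
        for alt_i, alt in enumerate(alts, start=1):
            if len(variant.REF) != 1 or len(alt) != 1:
                n_indels += 1
                continue
            ref_n, alt_n, ctx_n = _normalize_record(variant.REF, alt, context)
            records.append(
                SnvRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=ref_n,
                    alt=alt_n,
                    tumor_alt=int(ad[t_idx][alt_i]),
                    tumor_depth=int(ad[t_idx][0]) + int(sum(ad[t_idx][1:])),
                    normal_alt=int(ad[n_idx][alt_i]),
                    normal_depth=int(ad[n_idx][0]) + int(sum(ad[n_idx][1:])),
                    context=ctx_n,
                )
            )
    if n_indels:
        logger.info("skipped %d indel allele(s) in %s", n_indels, vcf_path)
    return LoadedSnvs(records, n_indels_skipped=n_indels, n_multiallelic_split=n_split)


def write_snv_vcf(records: Iterable[SnvRecord], path, tumor_sample="TUMOR", normal_sample="NORMAL") -> None:
    """Write SNVs as a minimal VCF 4.2 with INFO/TNC and FORMAT/AD:DP."""
    records = list(records)
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TNC,Number=1,Type=String,Description="Pyrimidine-centred trinucleotide context">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tumor_sample}\t{normal_sample}\n"
        )
        for r in sorted(records, key=lambda x: (chroms.index(x.chrom), x.pos)):
            info = f"TNC={r.context}" if r.context else "."
            t_ad = f"{r.tumor_depth - r.tumor_alt},{r.tumor_alt}"
            n_ad = f"{r.normal_depth - r.normal_alt},{r.normal_alt}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tAD:DP\t"
                f"{t_ad}:{r.tumor_depth}\t{n_ad}:{r.normal_depth}\n"
            )


def load_segments(tsv_path) -> List[CnSegment]:
    """Read allele-specific copy-number segments (1-based inclusive TSV).

    Returns 0-based half-open segments, sorted, with per-chromosome
    non-overlap enforced.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns {missing}")
    segments = [
        CnSegment(
            chrom=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            major=int(row.major),
            minor=int(row.minor),
            clonal_fraction=float(row.clonal_fraction),
        )
        for row in df.itertuples()
    ]
    segments.sort(key=lambda s: (s.chrom, s.start))
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start + 1}-{a.end} and {b.start + 1}-{b.end}"
                )
    return segments


def write_segments(segments: Sequence[CnSegment], path) -> None:
    """Write segments back to the 1-based inclusive TSV dialect."""
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start + 1,
                "end": s.end,
                "major": s.major,
                "minor": s.minor,
                "clonal_fraction": s.clonal_fraction,
            }
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_catalog(tsv_path) -> SignatureCatalog:
    """Read a 96-row signature catalog TSV (first column = channel labels)."""
    df = pd.read_csv(tsv_path, sep="\t")
    label_col = df.columns[0]
    df = df.set_index(label_col)
    try:
        df = df.loc[list(CHANNELS)]
    except KeyError as exc:
        raise ValueError(f"catalog rows do not cover the 96 channels: {exc}") from exc
    return SignatureCatalog(list(df.columns), df.to_numpy(dtype=float))


def write_catalog(catalog: SignatureCatalog, path) -> None:
    df = pd.DataFrame(catalog.probs, index=list(CHANNELS), columns=catalog.names)
    df.index.name = "Type"
    df.to_csv(path, sep="\t")


def load_pon(tsv_path) -> set:
    """Panel-of-normals sites as a set of (chrom, pos, ref, alt)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples()
    }


REPORT_SCHEMA_VERSION = 1

_SCALAR_REPORT_FIELDS = [
    "sample_id", "burden_per_mb", "loh_state", "loh_extent", "mutant_copies",
    "wildtype_copies", "pi", "ci_low", "ci_high", "n_pre", "n_post",
    "n_subclonal", "n_pre_clock", "n_post_clock", "age_at_gain_years",
    "telomere_tn_ratio", "flags",
]


def emit_report(per_tumor_results: Sequence[dict], path) -> tuple:
    """Write cohort results as a TSV (flat scalars) and JSON (full nested).

    ``path`` is a basename; ``<path>.tsv`` and ``<path>.json`` are written.
    Returns the two paths.
    """
    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    json_path = path.with_suffix(".json")

    rows = []
    for res in per_tumor_results:
        row = {}
        for key in _SCALAR_REPORT_FIELDS:
            val = res.get(key)
            if isinstance(val, (list, set, tuple)):
                val = ";".join(str(v) for v in sorted(val)) if val else ""
            row[key] = val
        rows.append(row)
    pd.DataFrame(rows, columns=_SCALAR_REPORT_FIELDS).to_csv(tsv_path, sep="\t", index=False)

    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "results": [_jsonable(res) for res in per_tumor_results],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path


def read_report_json(json_path) -> list:
    with open(json_path) as fh:
        payload = json.load(fh)
    return payload["results"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
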