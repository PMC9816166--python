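"""Somatic-call QC filter cascade and mutation-burden computation.

Each filter is a pure predicate over a record (plus optional per-site
annotations), so the cascade is order-invariant. Removed records are logged
with the flag combination that fired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .types import SnvRecord

logger = logging.getLogger(__name__)

GENOME_SIZE_MB = 2800.0  # haploid genome span used to express burden per Mb


@dataclass
class FilterAnnotation:
    """Mapping-quality annotations for one site.

    ``excessive_depth`` may be supplied precomputed, or derived from
    ``normal_depth`` against a chromosome-median depth (see
    :func:`annotate_excessive_depth`).
    """

    nonunique_map_frac: float = 1.0
    multimap_cluster: bool = False
    excessive_depth: bool = False
    dust_score: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nonunique_map_frac <= 1.0):
            raise ValueError("nonunique_map_frac out of [0,1]")
        if self.dust_score < 0:
            raise ValueError("dust_score must be >= 0")


def depth_normal_filter(
    snvs: Iterable[SnvRecord], min_depth: int = 10, max_normal_alt: int = 1
) -> List[SnvRecord]:
    """Keep records with >= ``min_depth`` reads in both tumor and normal and
    at most ``max_normal_alt`` variant reads in the matched normal."""
    kept = []
    for r in snvs:
        if (
            r.tumor_depth >= min_depth
            and r.normal_depth >= min_depth
            and r.normal_alt <= max_normal_alt
        ):
            kept.append(r)
        else:
            logger.debug("depth/normal filter removed %s:%d", r.chrom, r.pos)
    return kept


def mapping_flags(
    annotation: FilterAnnotation,
    min_unique_frac: float = 0.70,
    max_dust: int = 60,
) -> Set[str]:
    """Which of the four mapping-quality cutoffs fire for one site."""
    flags = set()
    if annotation.nonunique_map_frac < min_unique_frac:
        flags.add("nonunique_mapping")
    if annotation.multimap_cluster:
        flags.add("multimap_cluster")
    if annotation.excessive_depth:
        flags.add("excessive_depth")
    if annotation.dust_score > max_dust:
        flags.add("low_complexity")
    return flags


def mapping_filter(
    snvs: Iterable[SnvRecord],
    annotations: Dict[Tuple[str, int], FilterAnnotation],
    min_unique_frac: float = 0.70,
    max_dust: int = 60,
    max_flags: int = 1,
) -> List[SnvRecord]:
    """Remove records failing at least 2 of the 4 mapping cutoffs:
    <70% uniquely mapping reads, multi-mapping cluster (tumor and normal),
    excessively high depth, DUST score > 60."""
    kept = []
    for r in snvs:
        key = (r.chrom, r.pos)
        if key not in annotations:
            raise ValueError(f"no filter annotation for site {r.chrom}:{r.pos}")
        flags = mapping_flags(annotations[key], min_unique_frac, max_dust)
        if len(flags) > max_flags:
            logger.debug(
                "mapping filter removed %s:%d (%s)", r.chrom, r.pos, ",".join(sorted(flags))
            )
        else:
            kept.append(r)
    return kept


def annotate_excessive_depth(
    snvs: Sequence[SnvRecord], fold: float = 3.0
) -> Dict[Tuple[str, int], bool]:
    """Flag sites whose normal depth exceeds ``fold`` x the chromosome-median
    normal depth — an explicit proxy for 'excessively high mapping depth'."""
    import numpy as np

    by_chrom: Dict[str, list] = {}
    for r in snvs:
        by_chrom.setdefault(r.chrom, []).append(r.normal_depth)
    medians = {c: float(np.median(d)) for c, d in by_chrom.items()}
    return {
        (r.chrom, r.pos): r.normal_depth > fold * medians[r.chrom] for r in snvs
    }


def panel_of_normals_filter(
    snvs: Iterable[SnvRecord], pon_sites: Set[Tuple[str, int, str, str]]
) -> List[SnvRecord]:
    """Remove variants seen in the panel of normals (exact chrom/pos/ref/alt)."""
    kept = []
    for r in snvs:
        if (r.chrom, r.pos, r.ref, r.alt) in pon_sites:
            logger.debug("PON filter removed %s:%d %s>%s", r.chrom, r.pos, r.ref, r.alt)
        else:
            kept.append(r)
    return kept


def apply_filter_cascade(
    snvs: Sequence[SnvRecord],
    annotations: Optional[Dict[Tuple[str, int], FilterAnnotation]] = None,
    pon_sites: Optional[Set[Tuple[str, int, str, str]]] = None,
    min_depth: int = 10,
    max_normal_alt: int = 1,
) -> List[SnvRecord]:
    """Depth/normal, mapping-quality and panel-of-normals filters in sequence.

    The three stages are pure predicates, so the composition does not depend
    on their order.
    """
    out = depth_normal_filter(snvs, min_depth=min_depth, max_normal_alt=max_normal_alt)
    if annotations is not None:
        out = mapping_filter(out, annotations)
    if pon_sites is not None:
        out = panel_of_normals_filter(out, pon_sites)
    logger.info("filter cascade: %d -> %d records", len(snvs), len(out))
    return out


def mutation_burden(n_passing: int, genome_size_mb: float = GENOME_SIZE_MB) -> float:
    """Mutations per megabase: passing call count over a 2800 Mb genome."""
    if n_passing < 0:
        raise ValueError("negative mutation count")
    return n_passing / genome_size_mb
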