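"""Per-tumor and cohort orchestration: filters -> LOH -> multiplicity ->
signatures -> timing (-> telomere), driven by a YAML-able config dict.

The pipeline is a pure function of (inputs, config, seed): rerunning with the
same config produces an identical report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import filters as flt
from . import io
from .loh import assign_mutant_allele, classify_locus, vaf_shift_test
from .signatures import (
    count_contexts,
    fit_exposures,
    is_clock_mutation,
    mutation_posteriors,
)
from .simulate import fixture_catalog
from .telomere import estimate_from_reads, tn_ratio
from .timing import time_gain_mixture
from .types import LohState

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("sample_id", "purity", "vcf", "segments", "locus")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require(config: dict, field: str):
    if field not in config or config[field] is None:
        raise ValueError(f"config missing required field {field!r}")
    return config[field]


def _load_annotations(path) -> Dict[tuple, flt.FilterAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos)): flt.FilterAnnotation(
            nonunique_map_frac=float(getattr(r, "nonunique_map_frac", 1.0)),
            multimap_cluster=bool(getattr(r, "multimap_cluster", False)),
            excessive_depth=bool(getattr(r, "excessive_depth", False)),
            dust_score=int(getattr(r, "dust_score", 0)),
        )
        for r in df.itertuples()
    }


def run_tumor(config: dict) -> dict:
    """Run the full per-tumor analysis; returns the report dict."""
    for field in REQUIRED_FIELDS:
        _require(config, field)
    sample_id = config["sample_id"]
    purity = float(config["purity"])
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity out of (0,1]: {purity}")

    flags: List[str] = []

    loaded = io.load_snvs(
        config["vcf"],
        config.get("tumor_sample", "TUMOR"),
        config.get("normal_sample", "NORMAL"),
    )
    segments = io.load_segments(config["segments"])
    catalog = (
        io.load_catalog(config["catalog"]) if config.get("catalog") else fixture_catalog()
    )

    fcfg = config.get("filters", {}) or {}
    annotations = (
        _load_annotations(fcfg["annotations"]) if fcfg.get("annotations") else None
    )
    pon = io.load_pon(fcfg["pon"]) if fcfg.get("pon") else None
    snvs = flt.apply_filter_cascade(
        loaded.records,
        annotations=annotations,
        pon_sites=pon,
        min_depth=int(fcfg.get("min_depth", 10)),
        max_normal_alt=int(fcfg.get("max_normal_alt", 1)),
    )
    burden = flt.mutation_burden(len(snvs))

    locus_cfg = config["locus"]
    # locus supplied 1-based inclusive, converted here
    locus = (str(locus_cfg["chrom"]), int(locus_cfg["start"]) - 1, int(locus_cfg["end"]))
    chrom_length = int(_require(config, "chrom_length"))
    loh = classify_locus(
        segments, locus, chrom_length,
        whole_chrom_frac=float(config.get("whole_chrom_frac", 0.95)),
        locus_name=config.get("locus_name", "TP53"),
    )
    if loh.low_confidence:
        flags.append("loh_low_confidence")

    # signatures on the genome-wide filtered SNVs
    counts = count_contexts(snvs)
    fit = fit_exposures(counts, catalog)
    if fit.non_identifiable:
        flags.append("exposures_non_identifiable")
    posteriors = mutation_posteriors(snvs, fit, catalog) if snvs else np.zeros((0, catalog.n_signatures))

    # germline allele assignment + VAF shift
    germline_out = None
    g = config.get("germline")
    if g:
        p_shift = vaf_shift_test(
            int(g["germline_alt"]), int(g["germline_depth"]),
            int(g["tumor_alt"]), int(g["tumor_depth"]),
        )
        assignment = assign_mutant_allele(
            germline_vaf=int(g["germline_alt"]) / int(g["germline_depth"]),
            tumor_alt=int(g["tumor_alt"]),
            tumor_depth=int(g["tumor_depth"]),
            purity=purity,
            major=loh.major,
            minor=loh.minor,
        )
        if assignment.tie:
            flags.append("mutant_allele_tie")
        germline_out = {
            "vaf_shift_p": p_shift,
            "mutant_allele": assignment.allele,
            "expected_vaf": assignment.expected_vaf,
        }

    # timing of the gain on the locus segment
    timing_out = None
    n_pre = n_post = n_sub = None
    n_pre_clock = n_post_clock = None
    boot_cfg = config.get("bootstrap", {}) or {}
    locus_chrom, locus_start, locus_end = locus
    seg = next(
        (s for s in segments
         if s.chrom == locus_chrom and s.start < locus_end and locus_start < s.end),
        None,
    )
    timeable = (
        seg is not None
        and loh.state in (LohState.CN_LOH, LohState.GAIN_NO_LOH)
        and (seg.major, seg.minor) in {(2, 0), (2, 1), (2, 2)}
    )
    if timeable:
        on_seg = [
            (i, r) for i, r in enumerate(snvs)
            if r.chrom == seg.chrom and seg.contains(r.pos - 1)
        ]
        idx = [i for i, _ in on_seg]
        seg_snvs = [r for _, r in on_seg]
        if seg_snvs:
            alt = np.array([r.tumor_alt for r in seg_snvs])
            depth = np.array([r.tumor_depth for r in seg_snvs])
            seed = boot_cfg.get("seed")
            B = int(boot_cfg.get("B", 200))
            result = time_gain_mixture(alt, depth, purity, seg, B=B, seed=seed)
            clock_mask = np.array([
                is_clock_mutation(
                    r, {n: posteriors[idx[j], k] for k, n in enumerate(catalog.names)}
                )
                for j, r in enumerate(seg_snvs)
            ])
            clock_result = time_gain_mixture(
                alt, depth, purity, seg, B=B,
                seed=None if seed is None else seed + 1,
                mask=clock_mask,
            )
            if result.low_confidence:
                flags.append("timing_low_confidence")
            if result.overflow:
                flags.append("timing_overflow")
            n_pre, n_post, n_sub = result.n_pre, result.n_post, result.n_subclonal
            n_pre_clock, n_post_clock = clock_result.n_pre, clock_result.n_post
            timing_out = {
                "pi": result.pi,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "n_boot": result.n_boot,
                "cn_state": list(result.cn_state),
                "pi_clock": clock_result.pi,
                "clock_ci": [clock_result.ci_low, clock_result.ci_high],
            }
    else:
        flags.append("not_timeable")

    age_at_gain = None
    if timing_out is not None and config.get("age_at_dx"):
        from .timing import chronological_bound

        age_at_gain = chronological_bound(
            n_pre_clock, n_post_clock, seg.major, seg.minor, float(config["age_at_dx"])
        )

    telo_ratio = None
    tcfg = config.get("telomere")
    if tcfg:
        from .simulate import read_fastq

        t_est = estimate_from_reads(read_fastq(tcfg["tumor_fastq"]), float(tcfg["g_gc"]))
        n_est = estimate_from_reads(read_fastq(tcfg["normal_fastq"]), float(tcfg["g_gc"]))
        telo_ratio = tn_ratio(t_est.length_kb, n_est.length_kb)

    return {
        "sample_id": sample_id,
        "group": config.get("group"),
        "age_at_dx": config.get("age_at_dx"),
        "n_input_snvs": len(loaded.records),
        "n_indels_skipped": loaded.n_indels_skipped,
        "n_passing": len(snvs),
        "burden_per_mb": burden,
        "loh_state": loh.state.value,
        "loh_extent": loh.extent.value,
        "mutant_copies": loh.mutant_copies,
        "wildtype_copies": loh.wildtype_copies,
        "exposures": fit.as_dict(),
        "germline": germline_out,
        "pi": None if timing_out is None else timing_out["pi"],
        "ci_low": None if timing_out is None else timing_out["ci_low"],
        "ci_high": None if timing_out is None else timing_out["ci_high"],
        "timing": timing_out,
        "n_pre": n_pre,
        "n_post": n_post,
        "n_subclonal": n_sub,
        "n_pre_clock": n_pre_clock,
        "n_post_clock": n_post_clock,
        "age_at_gain_years": age_at_gain,
        "telomere_tn_ratio": telo_ratio,
        "flags": flags,
        "parameters": {
            "purity": purity,
            "filters": {
                "min_depth": int(fcfg.get("min_depth", 10)),
                "max_normal_alt": int(fcfg.get("max_normal_alt", 1)),
            },
            "whole_chrom_frac": float(config.get("whole_chrom_frac", 0.95)),
            "bootstrap": {"B": int(boot_cfg.get("B", 200)), "seed": boot_cfg.get("seed")},
            "clonality_note": "clonality from the binomial CCF model, not phylogenetic clustering",
        },
    }


def run_cohort(configs: Sequence[dict]) -> dict:
    """Run every tumor, assemble the cohort table and group statistics."""
    ids = [c.get("sample_id") for c in configs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicated sample ids: {sorted(dupes)}")
    results = [run_tumor(c) for c in configs]

    stats_out: Dict[str, Optional[float]] = {
        "rank_sum_p": None, "pearson_r": None, "pearson_p": None, "note": None,
    }
    by_group: Dict[str, List[float]] = {}
    for res in results:
        if res["pi"] is not None and res.get("group") is not None:
            by_group.setdefault(str(res["group"]), []).append(res["pi"])
    if len(by_group) == 2:
        from .timing import compare_timing_groups

        g1, g2 = sorted(by_group)
        stats_out["rank_sum_p"] = compare_timing_groups(by_group[g1], by_group[g2])
        stats_out["groups"] = [g1, g2]
    elif len(by_group) < 2:
        stats_out["note"] = "fewer than two labelled groups: comparison skipped"

    pairs = [
        (res["pi"], float(res["age_at_dx"]))
        for res in results
        if res["pi"] is not None and res.get("age_at_dx") is not None
    ]
    if len(pairs) >= 3:
        from .timing import correlate_age

        r, p = correlate_age([x for x, _ in pairs], [y for _, y in pairs])
        stats_out["pearson_r"], stats_out["pearson_p"] = r, p

    return {"results": results, "stats": stats_out}
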