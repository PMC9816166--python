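"""End-to-end recovery benchmarks under the study conditions.

Each routine simulates tumors with the generator's study-condition defaults
(purity 0.7, 60x coverage, 2000 clonal SNVs per tumor unless a routine's
scenario states otherwise), runs the package's own estimators, and measures
recovery against the planted truth. They are used by the acceptance tests
and the reproduction script; seeds are explicit everywhere.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .multiplicity import assign_multiplicities, fit_multiplicity_mixture
from .signatures import fit_exposures
from .simulate import (
    TelomereSimParams,
    fixture_catalog,
    multiplicity_weights,
    simulate_segment_readcounts,
    simulate_telomere_reads,
)
from .telomere import estimate_from_reads, tn_ratio
from .timing import molecular_time

TIMED_STATES = ((2, 0), (2, 1), (2, 2))
PI_GRID = (0.05, 0.25, 0.5, 0.75, 0.95)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n)


def estimate_pi_from_readcounts(
    alt: np.ndarray, depth: np.ndarray, purity: float, major: int, minor: int
) -> float:
    """The package's timing path: mixture fit -> soft counts -> closed form."""
    mix = fit_multiplicity_mixture(alt, depth, purity, major + minor, major)
    sc = mix.soft_counts
    return molecular_time(sc["n_pre"], sc["n_post"], major, minor)


def timing_recovery(
    seed: int,
    states: Sequence[Tuple[int, int]] = TIMED_STATES,
    pi_grid: Sequence[float] = PI_GRID,
    n_tumors: int = 50,
    n_mutations: int = 2000,
    purity: float = 0.7,
    depth: float = 60.0,
) -> Dict[Tuple[int, int, float], float]:
    """Mean recovered gain time per (major, minor, pi_true) cell."""
    out: Dict[Tuple[int, int, float], float] = {}
    for major, minor in states:
        for pi_true in pi_grid:
            seeds = _child_seeds(seed + major * 1000 + minor * 100 + int(pi_true * 1e4), n_tumors)
            estimates = []
            for s in seeds:
                rng = np.random.default_rng(int(s))
                sim = simulate_segment_readcounts(
                    rng, n_mutations, major, minor, pi_true, purity, depth,
                    subclonal_fraction=0.0,
                )
                estimates.append(
                    estimate_pi_from_readcounts(sim["alt"], sim["depth"], purity, major, minor)
                )
            out[(major, minor, pi_true)] = float(np.mean(estimates))
    return out


def closed_form_vs_lineage(
    seed: int,
    n_mutations: int = 100_000,
    states: Sequence[Tuple[int, int]] = TIMED_STATES,
    pi_grid: Sequence[float] = (0.25, 0.5, 0.75),
) -> float:
    """Max |pi_hat - pi_true| with exact multiplicities drawn from the
    lineage weights — isolates the closed forms from read noise."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for major, minor in states:
        for pi_true in pi_grid:
            w = multiplicity_weights(major, minor, pi_true)
            ms = np.array(sorted(w))
            p = np.array([w[m] for m in ms])
            draws = rng.choice(ms, size=n_mutations, p=p / p.sum())
            n2 = int((draws >= 2).sum())
            n1 = int((draws == 1).sum())
            worst = max(worst, abs(molecular_time(n2, n1, major, minor) - pi_true))
    return worst


def multiplicity_accuracy(
    seed: int,
    purities: Sequence[float] = (0.6, 0.8, 1.0),
    depth: float = 80.0,
    n_mutations: int = 5000,
    pi_true: float = 0.4,
) -> Dict[float, float]:
    """Fraction of mutations whose assigned multiplicity equals the planted
    truth on a (2,0) segment."""
    out = {}
    for i, purity in enumerate(purities):
        rng = np.random.default_rng(seed + i)
        sim = simulate_segment_readcounts(
            rng, n_mutations, 2, 0, pi_true, purity, depth, subclonal_fraction=0.0
        )
        arrays = assign_multiplicities(sim["alt"], sim["depth"], purity, 2, 2)
        out[purity] = float(np.mean(arrays["m"] == sim["m_true"]))
    return out


def exposure_recovery(
    seed: int,
    true_exposures: Sequence[float] = (0.2, 0.5, 0.3),
    n_mutations: int = 5000,
) -> Tuple[float, bool]:
    """(L1 error of refitted exposures, EM log-likelihood monotone?)."""
    catalog = fixture_catalog()
    rng = np.random.default_rng(seed)
    e = np.asarray(true_exposures, float)
    counts = rng.multinomial(n_mutations, catalog.probs @ e)
    fit = fit_exposures(counts, catalog)
    l1 = float(np.abs(fit.exposures - e).sum())
    monotone = bool(np.all(np.diff(fit.loglik_trace) >= -1e-9))
    return l1, monotone


def bootstrap_coverage(
    seed: int,
    n_tumors: int = 200,
    pi_true: float = 0.5,
    n_mutations: int = 2000,
    purity: float = 0.7,
    depth: float = 60.0,
    B: int = 200,
) -> float:
    """Fraction of simulated tumors whose 95% bootstrap CI covers pi_true."""
    from .timing import time_gain_mixture
    from .types import CnSegment

    seg = CnSegment("17", 0, 81_195_210, 2, 0)
    seeds = _child_seeds(seed, n_tumors)
    covered = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        sim = simulate_segment_readcounts(
            rng, n_mutations, 2, 0, pi_true, purity, depth, subclonal_fraction=0.0
        )
        res = time_gain_mixture(
            sim["alt"], sim["depth"], purity, seg, B=B, seed=int(s) % (2**31)
        )
        if res.ci_low <= pi_true <= res.ci_high:
            covered += 1
    return covered / n_tumors


def telomere_ratio_recovery(
    seed: int,
    planted_ratio: float = 3.0,
    base_fraction: float = 0.01,
    n_background: int = 4000,
    g_gc: float = 1.0e6,
) -> float:
    """Recovered T/N ratio from FASTQ-level simulation with planted
    telomere content planted_ratio x higher in the tumor."""
    tumor = simulate_telomere_reads(
        TelomereSimParams(
            n_background=n_background,
            telomeric_fraction=base_fraction * planted_ratio,
        ),
        seed,
    )
    normal = simulate_telomere_reads(
        TelomereSimParams(n_background=n_background, telomeric_fraction=base_fraction),
        seed + 1,
    )
    t = estimate_from_reads(tumor, g_gc=g_gc)
    n = estimate_from_reads(normal, g_gc=g_gc)
    return tn_ratio(t.length_kb, n.length_kb)
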