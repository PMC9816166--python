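"""Per-mutation copy number (multiplicity), CCF and clonality.

The read model: a clonal mutation present on ``m`` of the ``cn_tot`` tumor
copies at tumor purity rho is expected at variant allele fraction

    VAF = (m * rho + m_normal * (1 - rho)) / (rho * cn_tot + 2 * (1 - rho))

where ``m_normal`` is the number of mutant copies carried by normal cells
(0 for somatic variants, 1 for a heterozygous germline variant). Multiplicity
is assigned by comparing binomial likelihoods of the observed alt count under
each candidate m (plus a subclonal branch at m=1), with a flat prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import MultiplicityCall

VAF_CAP_EPS = 0.01  # sequencing-error allowance: expected VAF capped at 1 - eps
DEFAULT_CLONAL_THRESHOLD = 0.8
DEFAULT_SUBCLONAL_CCF_GRID = np.round(np.linspace(0.1, 0.7, 13), 3)
CCF_CLIP = 1.2


def expected_vaf(
    m: float,
    purity: float,
    cn_tot: int,
    normal_mutant_copies: float = 0.0,
    cap_eps: float = VAF_CAP_EPS,
) -> float:
    """Expected variant allele fraction of a clonal mutation at multiplicity m.

    Capped at ``1 - cap_eps`` so that homozygous states retain nonzero
    likelihood under rare reference-supporting error reads.
    """
    if cn_tot == 0 and normal_mutant_copies == 0 and purity == 1.0:
        raise ValueError("cn_tot=0 with full purity: no DNA to sequence")
    if m < 0:
        raise ValueError("multiplicity must be >= 0")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if cn_tot < 1 and purity == 1.0:
        raise ValueError("cn_tot must be >= 1 in pure tumor")
    denom = purity * cn_tot + 2.0 * (1.0 - purity)
    if denom <= 0:
        raise ValueError("no sequenced copies at this locus")
    vaf = (m * purity + normal_mutant_copies * (1.0 - purity)) / denom
    return min(vaf, 1.0 - cap_eps)


def mutation_copy_number(
    tumor_alt: int, tumor_depth: int, purity: float, cn_tot: int
) -> float:
    """Continuous mutation copy number: VAF * (rho*cn_tot + 2(1-rho)) / rho."""
    if purity <= 0:
        raise ValueError("purity must be > 0")
    if tumor_depth <= 0:
        raise ValueError("tumor_depth must be > 0")
    vaf = tumor_alt / tumor_depth
    return vaf * (purity * cn_tot + 2.0 * (1.0 - purity)) / purity


def _ccf_interval(alt: int, depth: int, scale: float, level: float = 0.95) -> tuple:
    """Clopper-Pearson interval for the CCF (= scale * VAF)."""
    a = (1.0 - level) / 2.0
    low = stats.beta.ppf(a, alt, depth - alt + 1) if alt > 0 else 0.0
    high = stats.beta.ppf(1.0 - a, alt + 1, depth - alt) if alt < depth else 1.0
    return low * scale, high * scale


def assign_multiplicity(
    tumor_alt: int,
    tumor_depth: int,
    purity: float,
    cn_tot: int,
    max_m: int,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    subclonal_ccf_grid: Optional[Sequence[float]] = None,
) -> MultiplicityCall:
    """Assign integer multiplicity, CCF and clonality to one mutation.

    Candidates are m in {1..max_m} at CCF=1 plus a subclonal branch (m=1,
    CCF averaged over a grid < 1); posterior is likelihood-proportional under
    a flat prior. A mutation is called clonal if its CCF point estimate
    reaches ``clonal_threshold`` or its 95% binomial CCF interval covers 1.
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1 (segment must carry DNA)")
    if tumor_depth <= 0:
        raise ValueError("tumor_depth must be > 0")
    if subclonal_ccf_grid is None:
        subclonal_ccf_grid = DEFAULT_SUBCLONAL_CCF_GRID

    ms = np.arange(1, max_m + 1)
    probs = np.array([expected_vaf(m, purity, cn_tot) for m in ms])
    lik = stats.binom.pmf(tumor_alt, tumor_depth, probs)

    denom = purity * cn_tot + 2.0 * (1.0 - purity)
    sub_probs = np.asarray(subclonal_ccf_grid) * purity / denom
    sub_lik = stats.binom.pmf(tumor_alt, tumor_depth, sub_probs).mean()

    weights = np.append(lik, sub_lik)
    total = weights.sum()
    if total <= 0:  # numerically impossible observation: fall back to flat
        weights = np.ones_like(weights)
        total = weights.sum()
    post = weights / total
    posterior = {str(m): float(p) for m, p in zip(ms, post[:-1])}
    posterior["subclonal"] = float(post[-1])

    # subclonal branch is still multiplicity 1 — fold it in for the argmax
    per_m = post[:-1].copy()
    per_m[0] += post[-1]
    m_hat = int(ms[np.argmax(per_m)])

    m_cont = mutation_copy_number(tumor_alt, tumor_depth, purity, cn_tot)
    ccf = float(np.clip(m_cont / m_hat, 0.0, CCF_CLIP))
    scale = denom / (purity * m_hat)
    ci_low, ci_high = _ccf_interval(tumor_alt, tumor_depth, scale)
    clonal = bool(ccf >= clonal_threshold or (ci_low <= 1.0 <= ci_high))

    return MultiplicityCall(
        m=m_hat, m_continuous=float(m_cont), ccf=ccf, clonal=clonal, posterior=posterior
    )


@dataclass
class MultiplicityMixture:
    """Segment-level mixture fit over multiplicity components.

    Components are the clonal multiplicities 1..max_m plus one subclonal
    component (CCF grid average); ``weights`` are the EM maximum-likelihood
    mixing proportions and ``responsibilities`` the per-mutation posterior
    over components (rows sum to 1). Soft (posterior-weighted) counts are the
    statistically consistent inputs for gain timing: hard argmax counts
    over-assign the minority component when the binomial components overlap.
    """

    max_m: int
    weights: np.ndarray  # (max_m + 1,), last entry = subclonal
    responsibilities: np.ndarray  # (n, max_m + 1)
    loglik: float
    n_iter: int

    @property
    def soft_counts(self) -> dict:
        """Expected counts: pre-gain (m>=2), post-gain (m=1), subclonal."""
        r = self.responsibilities
        return {
            "n_pre": float(r[:, 1:self.max_m].sum()),
            "n_post": float(r[:, 0].sum()),
            "n_subclonal": float(r[:, self.max_m].sum()),
        }


def fit_multiplicity_mixture(
    tumor_alt: np.ndarray,
    tumor_depth: np.ndarray,
    purity: float,
    cn_tot: int,
    max_m: int,
    subclonal_ccf_grid: Optional[Sequence[float]] = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> MultiplicityMixture:
    """EM fit of the multiplicity mixture weights on one segment.

    Component success rates are fixed by the read model; only the mixing
    proportions are estimated (flat initialisation).
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    if subclonal_ccf_grid is None:
        subclonal_ccf_grid = DEFAULT_SUBCLONAL_CCF_GRID
    alt = np.asarray(tumor_alt, dtype=np.int64)
    depth = np.asarray(tumor_depth, dtype=np.int64)
    if alt.size == 0:
        raise ValueError("no mutations to fit")
    if np.any(depth <= 0):
        raise ValueError("tumor_depth must be > 0")

    ms = np.arange(1, max_m + 1)
    probs = np.array([expected_vaf(m, purity, cn_tot) for m in ms])
    lik = stats.binom.pmf(alt[:, None], depth[:, None], probs[None, :])
    denom = purity * cn_tot + 2.0 * (1.0 - purity)
    sub_probs = np.asarray(subclonal_ccf_grid) * purity / denom
    sub_lik = stats.binom.pmf(alt[:, None], depth[:, None], sub_probs[None, :]).mean(axis=1)
    L = np.column_stack([lik, sub_lik])

    K = L.shape[1]
    w = np.full(K, 1.0 / K)
    loglik = -np.inf
    n_iter = 0
    resp = np.full_like(L, 1.0 / K)
    for n_iter in range(1, max_iter + 1):
        weighted = L * w[None, :]
        totals = weighted.sum(axis=1, keepdims=True)
        totals[totals <= 0] = 1e-300
        resp = weighted / totals
        w = resp.mean(axis=0)
        new_loglik = float(np.log(np.maximum(totals, 1e-300)).sum())
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return MultiplicityMixture(
        max_m=max_m, weights=w, responsibilities=resp, loglik=loglik, n_iter=n_iter
    )


def assign_multiplicities(
    tumor_alt: np.ndarray,
    tumor_depth: np.ndarray,
    purity: float,
    cn_tot: int,
    max_m: int,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    subclonal_ccf_grid: Optional[Sequence[float]] = None,
) -> dict:
    """Vectorised multiplicity assignment for all mutations on one segment.

    Same model as :func:`assign_multiplicity`; returns arrays
    ``{"m", "m_continuous", "ccf", "clonal"}``.
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    if subclonal_ccf_grid is None:
        subclonal_ccf_grid = DEFAULT_SUBCLONAL_CCF_GRID
    alt = np.asarray(tumor_alt, dtype=np.int64)
    depth = np.asarray(tumor_depth, dtype=np.int64)
    if np.any(depth <= 0):
        raise ValueError("tumor_depth must be > 0")

    ms = np.arange(1, max_m + 1)
    probs = np.array([expected_vaf(m, purity, cn_tot) for m in ms])
    # (n, max_m) clonal likelihoods
    lik = stats.binom.pmf(alt[:, None], depth[:, None], probs[None, :])
    denom = purity * cn_tot + 2.0 * (1.0 - purity)
    sub_probs = np.asarray(subclonal_ccf_grid) * purity / denom
    sub_lik = stats.binom.pmf(alt[:, None], depth[:, None], sub_probs[None, :]).mean(axis=1)

    per_m = lik.copy()
    per_m[:, 0] += sub_lik
    m_hat = ms[np.argmax(per_m, axis=1)]

    m_cont = (alt / depth) * denom / purity
    ccf = np.clip(m_cont / m_hat, 0.0, CCF_CLIP)

    scale = denom / (purity * m_hat)
    a = 0.025
    with np.errstate(invalid="ignore"):
        low = np.where(alt > 0, stats.beta.ppf(a, alt, depth - alt + 1), 0.0) * scale
        high = np.where(alt < depth, stats.beta.ppf(1 - a, alt + 1, depth - alt), 1.0) * scale
    clonal = (ccf >= clonal_threshold) | ((low <= 1.0) & (1.0 <= high))

    return {
        "m": m_hat.astype(int),
        "m_continuous": m_cont,
        "ccf": ccf,
        "clonal": clonal,
    }
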