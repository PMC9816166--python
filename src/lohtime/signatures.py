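"""Signature refitting against a fixed 96-context catalog.

Exposures are maximum-likelihood multinomial mixture weights, fitted by EM:
with catalog probabilities P(c|s) and exposures e_s, each iteration sets

    e_s <- sum_c n_c * P(s|c) / N,   P(s|c) = e_s P(c|s) / sum_s' e_s' P(c|s')

which never decreases the log-likelihood. Per-mutation signature posteriors
follow from the fitted exposures by Bayes' rule. De-novo signature discovery
(NMF) is out of scope: the catalog is an input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np

from .contexts import CHANNELS, channel_index, is_cpg_transition
from .types import SignatureCatalog, SnvRecord

logger = logging.getLogger(__name__)

CLOCK_SIGNATURES = ("SBS1", "SBS5")


def count_contexts(snvs: Iterable[SnvRecord]) -> np.ndarray:
    """Count mutations over the 96 pyrimidine-centred channels."""
    counts = np.zeros(96, dtype=np.int64)
    for r in snvs:
        if r.context is None:
            raise ValueError(f"missing trinucleotide context at {r.chrom}:{r.pos}")
        try:
            counts[channel_index(r.ref, r.alt, r.context)] += 1
        except ValueError as exc:
            raise ValueError(f"at {r.chrom}:{r.pos}: {exc}") from exc
    return counts


@dataclass
class ExposureFit:
    """Fitted exposure vector plus EM diagnostics."""

    names: List[str]
    exposures: np.ndarray
    loglik: float
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False, default=None)
    non_identifiable: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {n: float(e) for n, e in zip(self.names, self.exposures)}

    def __getitem__(self, name: str) -> float:
        return float(self.exposures[self.names.index(name)])


def fit_exposures(
    counts: np.ndarray,
    catalog: SignatureCatalog,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ExposureFit:
    """Maximum-likelihood exposures for a 96-channel count vector.

    Iterates EM until the log-likelihood improves by less than ``tol``.
    Raises on all-zero counts or on counts in channels no signature can emit.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"counts must be a 96-vector, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("negative channel count")
    n_total = counts.sum()
    if n_total == 0:
        raise ValueError("all-zero counts: nothing to fit")

    P = catalog.probs  # (96, S)
    S = catalog.n_signatures
    non_identifiable = False
    for i in range(S):
        for j in range(i + 1, S):
            if np.allclose(P[:, i], P[:, j], atol=1e-12):
                logger.warning(
                    "signatures %s and %s are identical: exposures not identifiable",
                    catalog.names[i], catalog.names[j],
                )
                non_identifiable = True

    support = P.sum(axis=1) > 0
    if np.any(counts[~support] > 0):
        bad = [CHANNELS[i] for i in np.where(~support & (counts > 0))[0]]
        raise ValueError(f"counts in channels no signature can emit: {bad}")

    e = np.full(S, 1.0 / S)
    trace = []
    loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = P @ e  # (96,)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_loglik = float(np.sum(counts[counts > 0] * np.log(mix[counts > 0])))
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
        # responsibility-weighted update
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(mix[:, None] > 0, P * e[None, :] / mix[:, None], 0.0)
        e = (counts[:, None] * resp).sum(axis=0) / n_total
    return ExposureFit(
        names=list(catalog.names),
        exposures=e,
        loglik=loglik,
        n_iter=n_iter,
        loglik_trace=np.asarray(trace),
        non_identifiable=non_identifiable,
    )


def _resolve_channel(context: Union[int, str, SnvRecord]) -> int:
    if isinstance(context, SnvRecord):
        return channel_index(context.ref, context.alt, context.context)
    if isinstance(context, (int, np.integer)):
        if not 0 <= int(context) < 96:
            raise ValueError(f"channel index {context} out of range")
        return int(context)
    if isinstance(context, str) and context in CHANNELS:
        return CHANNELS.index(context)
    raise ValueError(f"cannot resolve channel from {context!r}")


def mutation_posterior(
    context: Union[int, str, SnvRecord],
    exposures: Union[ExposureFit, Dict[str, float], Sequence[float]],
    catalog: SignatureCatalog,
) -> Dict[str, float]:
    """P(signature | channel) under the fitted exposures (Bayes' rule)."""
    c = _resolve_channel(context)
    if isinstance(exposures, ExposureFit):
        e = exposures.exposures
    elif isinstance(exposures, dict):
        e = np.array([exposures[n] for n in catalog.names], dtype=float)
    else:
        e = np.asarray(exposures, dtype=float)
    weights = e * catalog.probs[c, :]
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"channel {CHANNELS[c]} has zero mass under the fitted exposures"
        )
    post = weights / total
    return {n: float(p) for n, p in zip(catalog.names, post)}


def mutation_posteriors(
    snvs: Sequence[SnvRecord],
    exposures: Union[ExposureFit, Dict[str, float]],
    catalog: SignatureCatalog,
) -> np.ndarray:
    """Posterior matrix (n_snvs, n_signatures); rows sum to 1."""
    if isinstance(exposures, ExposureFit):
        e = exposures.exposures
    else:
        e = np.array([exposures[n] for n in catalog.names], dtype=float)
    idx = np.array([channel_index(r.ref, r.alt, r.context) for r in snvs])
    weights = catalog.probs[idx, :] * e[None, :]
    totals = weights.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = np.where(totals.ravel() <= 0)[0][0]
        r = snvs[bad]
        raise ValueError(f"zero-mass channel for mutation at {r.chrom}:{r.pos}")
    return weights / totals


def is_clock_mutation(
    snv: SnvRecord,
    posterior: Dict[str, float],
    clock_signatures: Sequence[str] = CLOCK_SIGNATURES,
    threshold: float = 0.5,
) -> bool:
    """Clock (aging-like) mutation rule: CpG C>T, or clock-signature posterior
    strictly above the threshold (ties at exactly 0.5 are not clock)."""
    if snv.context is not None and is_cpg_transition(snv.ref, snv.alt, snv.context):
        return True
    p_clock = sum(posterior.get(s, 0.0) for s in clock_signatures)
    return p_clock > threshold
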