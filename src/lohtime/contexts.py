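"""Trinucleotide-context machinery for the 96-channel SBS convention.

Single-base substitutions are reported on the pyrimidine strand: a G>A call
with flanking bases XY is folded onto the reverse-complement C>T call, so
every mutation lands in one of 6 substitution classes x 16 flank pairs = 96
channels, labelled ``A[C>A]A`` ... ``T[T>G]T`` in the standard catalog order
(C>A, C>G, C>T, T>A, T>C, T>G; flanks lexicographic).
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: the 96 channel labels in COSMIC order
CHANNELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _BASES for f3 in _BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def normalize_substitution(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Fold a substitution onto the pyrimidine strand.

    Parameters
    ----------
    ref, alt : single bases (any strand)
    context : trinucleotide centred on ``ref``

    Returns the (ref, alt, context) triple with ref in {C, T}.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in PYRIMIDINES:
        return ref, alt, context
    return _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(context)


def channel_index(ref: str, alt: str, context: str) -> int:
    """Map a substitution (any strand) to its 0..95 channel index."""
    ref, alt, context = normalize_substitution(ref, alt, context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise ValueError(f"malformed context/substitution: {label}") from None


def channel_label(index: int) -> str:
    return CHANNELS[index]


def is_cpg_transition(ref: str, alt: str, context: str) -> bool:
    """True for C>T substitutions at CpG sites (N[C>T]G after normalization)."""
    ref, alt, context = normalize_substitution(ref, alt, context)
    return ref == "C" and alt == "T" and context[2] == "G"
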