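"""Composition-category modes: basic Kmer and reverse-complement Kmer.

``kmer_vector`` counts the ``L - k + 1`` overlapping windows of length k
(step 1) and reports occurrence *frequencies* — counts divided by the
window total — so the vector sums to 1.  ``revkmer_vector`` (DNA only)
collapses every k-mer with its reverse complement into a single
strand-independent feature, labelled by the lexicographic minimum of the
pair; for odd k there are ``4**k / 2`` classes, for even k
``(4**k + 4**(k//2)) / 2`` (palindromes are their own class).
"""

from __future__ import annotations

import numpy as np

from .property_store import oligomers
from .seqio import Alphabet, FeatureVector, Sequence

__all__ = ["kmer_vector", "revkmer_vector", "kmer_counts", "revcomp", "canonical_kmers"]

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(kmer: str) -> str:
    """Reverse complement of a DNA k-mer."""
    return kmer.translate(_DNA_COMPLEMENT)[::-1]


def _check_k(seq: Sequence, k: int) -> None:
    if seq.alphabet is None:
        raise ValueError(f"sequence {seq.id!r} has no declared alphabet")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(seq):
        raise ValueError(
            f"sequence {seq.id!r} too short: k={k} exceeds length {len(seq)}"
        )


def kmer_counts(seq: Sequence, k: int) -> np.ndarray:
    """Raw window counts aligned to the lexicographic k-mer labels."""
    _check_k(seq, k)
    letters = seq.alphabet.letters
    a = len(letters)
    code = {ch: i for i, ch in enumerate(letters)}
    digits = np.array([code[ch] for ch in seq.residues], dtype=np.int64)
    # rolling base-A encoding of each window
    weights = a ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(digits, k) @ weights
    counts = np.bincount(windows, minlength=a**k).astype(float)
    return counts


def kmer_vector(seq: Sequence, k: int, raw_counts: bool = False) -> FeatureVector:
    """Occurrence frequencies of all ``A**k`` k-mers, lexicographic order.

    With ``raw_counts=True`` the unnormalized window counts are emitted
    instead (for downstream tools that renormalize themselves).
    """
    counts = kmer_counts(seq, k)
    values = counts if raw_counts else counts / counts.sum()
    return FeatureVector(
        mode="Kmer",
        params={"k": k, "raw_counts": raw_counts},
        labels=oligomers(seq.alphabet, k),
        values=values,
    )


def canonical_kmers(k: int) -> tuple[str, ...]:
    """Reverse-complement class representatives (lexicographic minima), sorted."""
    reps = {min(m, revcomp(m)) for m in oligomers(Alphabet.DNA, k)}
    return tuple(sorted(reps))


def revkmer_vector(seq: Sequence, k: int, raw_counts: bool = False) -> FeatureVector:
    """Strand-collapsed k-mer frequencies (DNA only).

    Each window's k-mer is attributed to its canonical class; class totals
    are divided by the overall window count, so values sum to 1.
    """
    if seq.alphabet is not Alphabet.DNA:
        raise ValueError(
            f"RevKmer is defined for DNA only, got {seq.alphabet and seq.alphabet.value}"
        )
    counts = kmer_counts(seq, k)
    labels = canonical_kmers(k)
    pos = {rep: i for i, rep in enumerate(labels)}
    collapsed = np.zeros(len(labels))
    for m, c in zip(oligomers(Alphabet.DNA, k), counts):
        collapsed[pos[min(m, revcomp(m))]] += c
    values = collapsed if raw_counts else collapsed / collapsed.sum()
    return FeatureVector(
        mode="RevKmer",
        params={"k": k, "raw_counts": raw_counts},
        labels=labels,
        values=values,
    )
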