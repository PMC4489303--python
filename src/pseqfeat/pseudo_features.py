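"""Pseudo-component modes: composition plus sequence-order correlation.

The pseudo-composition family augments a k-tuple composition vector with λ
correlation tiers that summarize how physicochemical properties co-vary
between positions j steps apart, mixed in with a weight w.  Two coupling
conventions exist:

*parallel* — one θ per lag tier, the property-averaged squared difference

    θ_j = (1/(T-j)) Σ_i Θ(i, i+j),   Θ(i, j) = (1/Λ) Σ_u [P_u(i) - P_u(j)]²

*series* — one τ per (lag, property) pair, the plain product

    τ_{(j-1)Λ+u} = (1/(T-j)) Σ_i P_u(i) · P_u(i+j)      (lag-major order)

where the track P_u(1..T), T = L - g + 1, reads the sequence through the
standardized index u, and Λ is the number of selected properties.

The final vector normalizes the composition frequencies f to sum 1 and sets

    d_u = f_u / (1 + wΦ)           u = 1..A**k
    d_{A**k+v} = w c_v / (1 + wΦ)  one per correlation value c_v

with Φ the sum of all correlation values, so every vector sums to exactly 1.
Dimension: A**k + λ (parallel) or A**k + λΛ (series).  λ = 0 degenerates to
the bare composition vector.

The classic named modes are fixed configurations of this engine: PseDNC is
(k=2, dinucleotide correlations, parallel, the six structural properties);
PseKNC keeps dinucleotide correlations while the composition part uses
k-tuples; PC-/SC-PseAAC use (k=1, residue correlations) with the classic
hydrophobicity/hydrophilicity(/side-chain mass) sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

from .autocorr_features import build_track
from .kmer_features import kmer_counts
from .property_store import PropertyIndex, oligomers
from .seqio import FeatureVector, Sequence

__all__ = ["CorrelationProfile", "parallel_theta", "series_tau", "pseudo_composition"]


@dataclass(frozen=True)
class CorrelationProfile:
    """λ (parallel) or λ·Λ (series) correlation values with their labels."""

    kind: str  # "parallel" | "series"
    lam: int
    labels: tuple[str, ...]
    values: np.ndarray


def _check_lam(lam: int, T: int, seq_id: str) -> None:
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam > T - 1:
        raise ValueError(
            f"sequence {seq_id!r} too short: lambda {lam} exceeds the maximum "
            f"legal value {T - 1} for its {T} oligomer positions"
        )


def parallel_theta(
    seq: Sequence, props: Seq[PropertyIndex], lam: int, g: int
) -> CorrelationProfile:
    """Parallel-correlation tiers θ_1..θ_λ (squared-difference coupling).

    Each θ_j >= 0 since it averages squared differences.
    """
    track = build_track(seq, props, g)
    P = track.values  # (Λ, T)
    T = P.shape[1]
    _check_lam(lam, T, seq.id)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = P[:, : T - j] - P[:, j:]
        theta[j - 1] = np.mean(diff**2, axis=0).sum() / (T - j)
    return CorrelationProfile(
        kind="parallel",
        lam=lam,
        labels=tuple(f"theta{j}" for j in range(1, lam + 1)),
        values=theta,
    )


def series_tau(
    seq: Sequence, props: Seq[PropertyIndex], lam: int, g: int
) -> CorrelationProfile:
    """Series-correlation values τ, lag-major / property-minor order."""
    track = build_track(seq, props, g)
    P = track.values
    T = P.shape[1]
    _check_lam(lam, T, seq.id)
    labels, vals = [], []
    for j in range(1, lam + 1):
        prods = P[:, : T - j] * P[:, j:]  # (Λ, T-j)
        for u, name in enumerate(track.names):
            vals.append(float(prods[u].sum()) / (T - j))
            labels.append(f"tau:lag{j}:{name}")
    return CorrelationProfile(
        kind="series", lam=lam, labels=tuple(labels), values=np.array(vals)
    )


def pseudo_composition(
    seq: Sequence,
    props: Seq[PropertyIndex],
    k: int,
    lam: int,
    w: float,
    kind: str = "parallel",
    corr_g: int | None = None,
    mode: str | None = None,
) -> FeatureVector:
    """Full pseudo-composition vector: k-tuple composition + λ tiers.

    ``corr_g`` is the oligomer length the correlations are computed on
    (defaults to k; PseKNC passes corr_g=2 for any k).  ``kind`` selects the
    parallel or series coupling.  With w = 0 or λ = 0 the vector reduces to
    the bare composition.
    """
    if w < 0:
        raise ValueError(f"weight w must be >= 0, got {w}")
    if kind not in ("parallel", "series"):
        raise ValueError(f"kind must be 'parallel' or 'series', got {kind!r}")
    if corr_g is None:
        corr_g = k
    counts = kmer_counts(seq, k)
    freqs = counts / counts.sum()
    if lam == 0:
        corr_labels: tuple[str, ...] = ()
        corr_vals = np.empty(0)
    else:
        profile = (parallel_theta if kind == "parallel" else series_tau)(
            seq, props, lam, corr_g
        )
        corr_labels, corr_vals = profile.labels, profile.values
    phi = float(corr_vals.sum())
    denom = 1.0 + w * phi
    values = np.concatenate([freqs / denom, w * corr_vals / denom])
    labels = oligomers(seq.alphabet, k) + corr_labels
    return FeatureVector(
        mode=mode or f"Pse({kind})",
        params={
            "k": k,
            "lamada": lam,
            "weight": w,
            "kind": kind,
            "corr_g": corr_g,
            "properties": tuple(p.name for p in props),
        },
        labels=labels,
        values=values,
    )
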