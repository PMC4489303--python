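"""Autocorrelation-category modes: one covariance engine, three families.

Reading a sequence through a physicochemical index turns it into a numeric
track ``P_u(1..T)`` with ``T = L - g + 1`` positions, where g is the
oligomer length the index is defined on (2 for DAC/DCC/DACC, 3 for
TAC/TCC/TACC, 1 for the protein AC/CC/ACC).  The same engine serves all
three mode families.

For a lag ℓ the auto covariance of property u is the mean product of
deviations from the track's own mean,

    AC(u, ℓ) = (1/(T-ℓ)) Σ_{i=1}^{T-ℓ} (P_u(i) - P̄_u)(P_u(i+ℓ) - P̄_u),

and the cross covariance pairs two distinct properties,

    CC(u1, u2, ℓ) = (1/(T-ℓ)) Σ (P_{u1}(i) - P̄_{u1})(P_{u2}(i+ℓ) - P̄_{u2}).

Conventions fixed here (the literature varies): the denominator is the
number of summed pairs T-ℓ, and the mean is the track's own arithmetic
mean.  Properties are standardized (z-scored over the full oligomer set)
before the covariance so magnitudes are comparable across indices.
Labels are property-major with lag innermost; ordered cross pairs
(u1, u2), u1 ≠ u2, are enumerated in input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

from .property_store import NormalizedIndex, PropertyIndex, normalize_index, oligomers
from .seqio import FeatureVector, Sequence

__all__ = [
    "OligomerTrack",
    "build_track",
    "auto_covariance",
    "cross_covariance",
    "auto_cross_covariance",
]


@dataclass(frozen=True)
class OligomerTrack:
    """Per-property value sequences read from one sequence.

    ``values`` has shape (n_properties, T) with T = L - g + 1; ``means``
    holds each property's own track mean P̄_u.
    """

    oligo_len: int
    names: tuple[str, ...]
    values: np.ndarray
    means: np.ndarray


def _normalized(props: Seq[PropertyIndex]) -> list[NormalizedIndex]:
    return [normalize_index(p) for p in props]


def build_track(seq: Sequence, props: Seq[PropertyIndex], g: int) -> OligomerTrack:
    """Read ``seq`` through each (standardized) index as a numeric track."""
    if seq.alphabet is None:
        raise ValueError(f"sequence {seq.id!r} has no declared alphabet")
    if not props:
        raise ValueError("at least one physicochemical property is required")
    norm = _normalized(props)
    for p in norm:
        if p.oligo_len != g:
            raise ValueError(
                f"property {p.name!r} is a {p.oligo_len}-mer index, engine needs {g}"
            )
    T = len(seq) - g + 1
    if T < 1:
        raise ValueError(f"sequence {seq.id!r} shorter than oligomer length {g}")
    oset = oligomers(seq.alphabet, g)
    pos = {o: i for i, o in enumerate(oset)}
    idx = np.array([pos[seq.residues[i : i + g]] for i in range(T)], dtype=np.int64)
    mat = np.stack([p.array()[idx] for p in norm])
    return OligomerTrack(
        oligo_len=g,
        names=tuple(p.name for p in norm),
        values=mat,
        means=mat.mean(axis=1),
    )


def _deviations(track: OligomerTrack) -> np.ndarray:
    # shifted-data centering: anchoring at the first track value keeps a
    # constant track exactly zero after mean subtraction (plain x - x.mean()
    # leaves ~1 ulp residue) and is better conditioned for large offsets
    shifted = track.values - track.values[:, :1]
    return shifted - shifted.mean(axis=1, keepdims=True)


def _check_lag(track: OligomerTrack, lag_max: int, seq_id: str) -> None:
    T = track.values.shape[1]
    if lag_max < 1:
        raise ValueError(f"lag must be >= 1, got {lag_max}")
    if lag_max >= T:
        raise ValueError(
            f"sequence {seq_id!r} too short: lag {lag_max} needs at least "
            f"{lag_max + 1} oligomer positions, track has {T}"
        )


def auto_covariance(
    seq: Sequence, props: Seq[PropertyIndex], lag_max: int, g: int, mode: str = "AC"
) -> FeatureVector:
    """AC(u, ℓ) for every property u and lag ℓ = 1..lag_max.

    Dimension ``len(props) * lag_max``, property-major / lag-minor labels
    ``AC:<prop>:lag<ℓ>``.
    """
    track = build_track(seq, props, g)
    _check_lag(track, lag_max, seq.id)
    dev = _deviations(track)
    T = dev.shape[1]
    labels, vals = [], []
    for u, name in enumerate(track.names):
        for lag in range(1, lag_max + 1):
            vals.append(float(dev[u, : T - lag] @ dev[u, lag:]) / (T - lag))
            labels.append(f"AC:{name}:lag{lag}")
    return FeatureVector(
        mode=mode,
        params={"lag": lag_max, "properties": track.names},
        labels=tuple(labels),
        values=np.array(vals),
    )


def cross_covariance(
    seq: Sequence, props: Seq[PropertyIndex], lag_max: int, g: int, mode: str = "CC"
) -> FeatureVector:
    """CC(u1, u2, ℓ) over ordered pairs of distinct properties.

    Dimension ``n * (n-1) * lag_max``; requires at least two properties.
    """
    if len(props) < 2:
        raise ValueError("cross covariance needs at least 2 properties")
    track = build_track(seq, props, g)
    _check_lag(track, lag_max, seq.id)
    dev = _deviations(track)
    T = dev.shape[1]
    labels, vals = [], []
    for u1, n1 in enumerate(track.names):
        for u2, n2 in enumerate(track.names):
            if u1 == u2:
                continue
            for lag in range(1, lag_max + 1):
                vals.append(float(dev[u1, : T - lag] @ dev[u2, lag:]) / (T - lag))
                labels.append(f"CC:{n1}:{n2}:lag{lag}")
    return FeatureVector(
        mode=mode,
        params={"lag": lag_max, "properties": track.names},
        labels=tuple(labels),
        values=np.array(vals),
    )


def auto_cross_covariance(
    seq: Sequence, props: Seq[PropertyIndex], lag_max: int, g: int, mode: str = "ACC"
) -> FeatureVector:
    """Concatenated auto then cross covariance; dimension ``n**2 * lag_max``."""
    ac = auto_covariance(seq, props, lag_max, g)
    cc = cross_covariance(seq, props, lag_max, g)
    return FeatureVector(
        mode=mode,
        params={"lag": lag_max, "properties": ac.params["properties"]},
        labels=ac.labels + cc.labels,
        values=np.concatenate([ac.values, cc.values]),
    )
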