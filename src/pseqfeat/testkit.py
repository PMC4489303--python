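"""Synthetic sequences and deliberately naive oracle implementations.

``random_sequences`` draws reproducible uniform sequences for property-based
testing.  ``oracle_suite`` recomputes every mode's vector with structurally
independent code — dictionary tallies, explicit double loops, explicit
normalization, no shared helpers with the engines — so engine/oracle
agreement is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
from typing import Sequence as Seq

import numpy as np

from .property_store import PropertyIndex
from .seqio import Alphabet, FeatureVector, ParameterSet, Sequence

__all__ = ["random_sequences", "oracle_suite"]


def random_sequences(
    alphabet: Alphabet,
    n: int,
    length_range: tuple[int, int],
    seed: int,
) -> list[Sequence]:
    """``n`` uniform random sequences with lengths in ``length_range`` (inclusive).

    Fully determined by ``seed``: the same call yields byte-identical
    batches, so any failing property-test instance can be replayed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    letters = alphabet.letters
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        residues = "".join(letters[j] for j in rng.integers(0, len(letters), size=L))
        out.append(Sequence(id=f"rand{i + 1}", residues=residues, alphabet=alphabet))
    return out


# ---------------------------------------------------------------------------
# naive building blocks (no imports from the engine modules)


def _all_oligos(alphabet: Alphabet, k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(alphabet.letters, repeat=k)]


def _naive_zscore(p: PropertyIndex) -> dict[str, float]:
    oligos = _all_oligos(p.alphabet, p.oligo_len)
    vals = [p.values[o] for o in oligos]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    sd = var**0.5
    return {o: (p.values[o] - mean) / sd for o in oligos}


def _naive_kmer_freqs(seq: Sequence, k: int) -> dict[str, float]:
    tally: dict[str, int] = {}
    for i in range(len(seq.residues) - k + 1):
        m = seq.residues[i : i + k]
        tally[m] = tally.get(m, 0) + 1
    total = sum(tally.values())
    return {m: tally.get(m, 0) / total for m in _all_oligos(seq.alphabet, k)}


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _naive_track(seq: Sequence, prop: PropertyIndex, g: int) -> list[float]:
    z = _naive_zscore(prop)
    return [z[seq.residues[i : i + g]] for i in range(len(seq.residues) - g + 1)]


def _naive_ac(track: list[float], lag_max: int) -> list[float]:
    T = len(track)
    mean = sum(track) / T
    out = []
    for lag in range(1, lag_max + 1):
        s = 0.0
        for i in range(T - lag):
            s += (track[i] - mean) * (track[i + lag] - mean)
        out.append(s / (T - lag))
    return out


def _naive_cc(t1: list[float], t2: list[float], lag_max: int) -> list[float]:
    T = len(t1)
    m1 = sum(t1) / T
    m2 = sum(t2) / T
    out = []
    for lag in range(1, lag_max + 1):
        s = 0.0
        for i in range(T - lag):
            s += (t1[i] - m1) * (t2[i + lag] - m2)
        out.append(s / (T - lag))
    return out


def _naive_theta(seq: Sequence, props: Seq[PropertyIndex], lam: int, g: int) -> list[float]:
    tracks = [_naive_track(seq, p, g) for p in props]
    T = len(tracks[0])
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(T - j):
            coupling = sum((tr[i] - tr[i + j]) ** 2 for tr in tracks) / len(tracks)
            total += coupling
        thetas.append(total / (T - j))
    return thetas


def _naive_tau(seq: Sequence, props: Seq[PropertyIndex], lam: int, g: int) -> list[float]:
    tracks = [_naive_track(seq, p, g) for p in props]
    T = len(tracks[0])
    taus = []
    for j in range(1, lam + 1):
        for tr in tracks:
            s = 0.0
            for i in range(T - j):
                s += tr[i] * tr[i + j]
            taus.append(s / (T - j))
    return taus


def _naive_pseudo(
    seq: Sequence,
    props: Seq[PropertyIndex],
    k: int,
    lam: int,
    w: float,
    kind: str,
    corr_g: int,
) -> list[float]:
    freqs = _naive_kmer_freqs(seq, k)
    comp = [freqs[m] for m in _all_oligos(seq.alphabet, k)]
    if lam == 0:
        corr: list[float] = []
    elif kind == "parallel":
        corr = _naive_theta(seq, props, lam, corr_g)
    else:
        corr = _naive_tau(seq, props, lam, corr_g)
    phi = sum(corr)
    denom = 1.0 + w * phi
    return [f / denom for f in comp] + [w * c / denom for c in corr]


# ---------------------------------------------------------------------------


def oracle_suite(
    mode: str,
    seq: Sequence,
    params: ParameterSet,
    props: Seq[PropertyIndex] = (),
) -> FeatureVector:
    """Naive recomputation of ``mode``'s vector for cross-validation.

    ``props`` are the raw property indices the engine was given (they are
    z-scored here independently).  Labels are omitted from comparison
    concerns: the oracle emits positional labels only.
    """
    residues = seq.residues
    if mode == "Kmer":
        freqs = _naive_kmer_freqs(seq, params.k)
        vals = [freqs[m] for m in _all_oligos(seq.alphabet, params.k)]
    elif mode == "RevKmer":
        tally: dict[str, float] = {}
        k = params.k
        nwin = len(residues) - k + 1
        for i in range(nwin):
            m = residues[i : i + k]
            rc = "".join(_COMP[c] for c in reversed(m))
            rep = m if m <= rc else rc
            tally[rep] = tally.get(rep, 0) + 1
        reps = sorted(
            {min(m, "".join(_COMP[c] for c in reversed(m)))
             for m in _all_oligos(Alphabet.DNA, k)}
        )
        vals = [tally.get(r, 0) / nwin for r in reps]
    elif mode in ("DAC", "TAC", "AC"):
        g = {"DAC": 2, "TAC": 3, "AC": 1}[mode]
        vals = []
        for p in props:
            vals.extend(_naive_ac(_naive_track(seq, p, g), params.lag))
    elif mode in ("DCC", "TCC", "CC"):
        g = {"DCC": 2, "TCC": 3, "CC": 1}[mode]
        tracks = [_naive_track(seq, p, g) for p in props]
        vals = []
        for a in range(len(props)):
            for b in range(len(props)):
                if a != b:
                    vals.extend(_naive_cc(tracks[a], tracks[b], params.lag))
    elif mode in ("DACC", "TACC", "ACC"):
        g = {"DACC": 2, "TACC": 3, "ACC": 1}[mode]
        sub_a = oracle_suite({"DACC": "DAC", "TACC": "TAC", "ACC": "AC"}[mode], seq, params, props)
        sub_c = oracle_suite({"DACC": "DCC", "TACC": "TCC", "ACC": "CC"}[mode], seq, params, props)
        vals = list(sub_a.values) + list(sub_c.values)
    elif mode in ("PseDNC", "PC-PseDNC-General", "PC-PseAAC", "PC-PseAAC-General"):
        k = {"PseDNC": 2, "PC-PseDNC-General": 2, "PC-PseAAC": 1, "PC-PseAAC-General": 1}[mode]
        vals = _naive_pseudo(seq, props, k, params.lamada, params.weight, "parallel", k)
    elif mode == "PC-PseTNC-General":
        vals = _naive_pseudo(seq, props, 3, params.lamada, params.weight, "parallel", 3)
    elif mode == "PseKNC":
        vals = _naive_pseudo(seq, props, params.k, params.lamada, params.weight, "parallel", 2)
    elif mode in ("SC-PseDNC-General", "SC-PseAAC", "SC-PseAAC-General"):
        k = 2 if mode == "SC-PseDNC-General" else 1
        vals = _naive_pseudo(seq, props, k, params.lamada, params.weight, "series", k)
    elif mode == "SC-PseTNC-General":
        vals = _naive_pseudo(seq, props, 3, params.lamada, params.weight, "series", 3)
    else:
        raise ValueError(f"oracle has no recipe for mode {mode!r}")
    return FeatureVector(
        mode=f"oracle:{mode}",
        params=params.as_dict(),
        labels=tuple(f"f{i + 1}" for i in range(len(vals))),
        values=np.array(vals, dtype=float),
    )
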