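"""Mode registry: the 28 published feature modes and the batch runner.

Fourteen DNA modes, six RNA modes and eight protein modes, each a fixed
configuration of one of the three engines (composition, covariance,
pseudo-composition).  Modes are addressed by (alphabet, name); the same
published name (e.g. ``Kmer``, ``DAC``) can exist for several alphabets.

Parameter schemas follow the interactive tool's conventions: k in 1..6 for
nucleic acids and 1..3 for protein by default (override with
``allow_unsafe_k=True`` for larger composition spaces), lag >= 1, λ >= 0,
w >= 0 with default 0.05.  Autocorrelation and the nucleotide "-General"
pseudo modes require an explicit property selection; PseDNC/PseKNC default
to the six dinucleotide structural properties and the PseAAC modes to the
classic hydrophobicity/hydrophilicity(/side-chain mass) sets.

Batch semantics are all-or-nothing: any invalid sequence aborts the whole
run, because a partially generated feature matrix corrupts downstream
machine learning silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from . import autocorr_features as _ac
from . import kmer_features as _km
from . import pseudo_features as _ps
from .property_store import PropertyIndex, resolve_properties
from .seqio import Alphabet, FeatureVector, ParameterSet, Sequence

__all__ = ["ModeSpec", "list_modes", "get_mode", "run_mode", "UnknownModeError"]


class UnknownModeError(KeyError):
    """Mode name not registered (for the given alphabet)."""


@dataclass(frozen=True)
class ModeSpec:
    """Registry entry binding a published mode name to an engine configuration."""

    name: str
    alphabet: Alphabet
    category: str  # "composition" | "autocorrelation" | "pseudo"
    description: str
    uses_k: bool = False
    fixed_k: int | None = None  # composition tuple size forced by the mode
    uses_lag: bool = False
    uses_lambda: bool = False
    corr_g: int | None = None  # oligomer length of the correlation track
    kind: str | None = None  # parallel | series (pseudo category)
    default_props: tuple[str, ...] = ()
    props_required: bool = False
    run: Callable[..., FeatureVector] = field(repr=False, default=None)  # type: ignore[assignment]
    dimension: Callable[[ParameterSet, int], int] = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def example_params(self) -> ParameterSet:
        """A legal worked parameter assignment for demonstration output."""
        if self.category == "composition":
            return ParameterSet(k=2)
        if self.category == "autocorrelation":
            props = self.default_props or ("(choose two built-in properties)",)
            return ParameterSet(lag=2, properties=props)
        return ParameterSet(lamada=3, weight=0.05, properties=self.default_props)


_REGISTRY: dict[tuple[Alphabet, str], ModeSpec] = {}


def _register(spec: ModeSpec) -> None:
    key = (spec.alphabet, spec.name)
    assert key not in _REGISTRY, f"duplicate mode {key}"
    _REGISTRY[key] = spec


def _k_cap(alphabet: Alphabet) -> int:
    return 3 if alphabet is Alphabet.PROTEIN else 6


_STRUCTURAL_6 = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")
_PSEAAC_3 = ("Hydrophobicity", "Hydrophilicity", "SideChainMass")
_PSEAAC_2 = ("Hydrophobicity", "Hydrophilicity")


def _make_kmer(alphabet: Alphabet) -> ModeSpec:
    return ModeSpec(
        name="Kmer",
        alphabet=alphabet,
        category="composition",
        description="occurrence frequencies of all k-mers (overlapping windows)",
        uses_k=True,
        run=lambda seq, p, props: _km.kmer_vector(seq, p.k),
        dimension=lambda p, n: alphabet.size**p.k,
    )


def _make_revkmer() -> ModeSpec:
    return ModeSpec(
        name="RevKmer",
        alphabet=Alphabet.DNA,
        category="composition",
        description="strand-independent k-mer frequencies (reverse complements collapsed)",
        uses_k=True,
        run=lambda seq, p, props: _km.revkmer_vector(seq, p.k),
        dimension=lambda p, n: len(_km.canonical_kmers(p.k)),
    )


def _make_cov(name: str, alphabet: Alphabet, g: int, engine: str) -> ModeSpec:
    runner = {
        "auto": _ac.auto_covariance,
        "cross": _ac.cross_covariance,
        "acc": _ac.auto_cross_covariance,
    }[engine]
    dim = {
        "auto": lambda p, n: n * p.lag,
        "cross": lambda p, n: n * (n - 1) * p.lag,
        "acc": lambda p, n: n * n * p.lag,
    }[engine]
    unit = {1: "residue", 2: "dinucleotide", 3: "trinucleotide"}[g]
    kind = {"auto": "auto", "cross": "cross", "acc": "auto-cross"}[engine]
    return ModeSpec(
        name=name,
        alphabet=alphabet,
        category="autocorrelation",
        description=f"{unit}-based {kind} covariance over selected indices",
        uses_lag=True,
        corr_g=g,
        props_required=True,
        run=lambda seq, p, props: runner(seq, props, p.lag, g, mode=name),
        dimension=dim,
    )


def _make_pseudo(
    name: str,
    alphabet: Alphabet,
    k: int | None,
    corr_g: int,
    kind: str,
    default_props: tuple[str, ...],
    props_required: bool,
    description: str,
) -> ModeSpec:
    def run(seq: Sequence, p: ParameterSet, props: list[PropertyIndex]) -> FeatureVector:
        kk = k if k is not None else p.k
        return _ps.pseudo_composition(
            seq,
            props,
            k=kk,
            lam=p.lamada,
            w=p.weight,
            kind=kind,
            corr_g=corr_g,
            mode=name,
        )

    def dim(p: ParameterSet, n: int) -> int:
        kk = k if k is not None else p.k
        comp = alphabet.size**kk
        return comp + (p.lamada if kind == "parallel" else p.lamada * n)

    return ModeSpec(
        name=name,
        alphabet=alphabet,
        category="pseudo",
        description=description,
        uses_k=k is None,
        fixed_k=k,
        uses_lambda=True,
        corr_g=corr_g,
        kind=kind,
        default_props=default_props,
        props_required=props_required,
        run=run,
        dimension=dim,
    )


def _build_registry() -> None:
    # --- DNA: 14 modes
    _register(_make_kmer(Alphabet.DNA))
    _register(_make_revkmer())
    for nm, g, eng in (
        ("DAC", 2, "auto"),
        ("DCC", 2, "cross"),
        ("DACC", 2, "acc"),
        ("TAC", 3, "auto"),
        ("TCC", 3, "cross"),
        ("TACC", 3, "acc"),
    ):
        _register(_make_cov(nm, Alphabet.DNA, g, eng))
    _register(
        _make_pseudo(
            "PseDNC", Alphabet.DNA, 2, 2, "parallel", _STRUCTURAL_6, False,
            "pseudo dinucleotide composition (six structural properties)",
        )
    )
    _register(
        _make_pseudo(
            "PseKNC", Alphabet.DNA, None, 2, "parallel", _STRUCTURAL_6, False,
            "pseudo k-tuple composition with dinucleotide correlation tiers",
        )
    )
    _register(
        _make_pseudo(
            "PC-PseDNC-General", Alphabet.DNA, 2, 2, "parallel", (), True,
            "general parallel-correlation pseudo dinucleotide composition",
        )
    )
    _register(
        _make_pseudo(
            "PC-PseTNC-General", Alphabet.DNA, 3, 3, "parallel", (), True,
            "general parallel-correlation pseudo trinucleotide composition",
        )
    )
    _register(
        _make_pseudo(
            "SC-PseDNC-General", Alphabet.DNA, 2, 2, "series", (), True,
            "general series-correlation pseudo dinucleotide composition",
        )
    )
    _register(
        _make_pseudo(
            "SC-PseTNC-General", Alphabet.DNA, 3, 3, "series", (), True,
            "general series-correlation pseudo trinucleotide composition",
        )
    )
    # --- RNA: 6 modes
    _register(_make_kmer(Alphabet.RNA))
    for nm, eng in (("DAC", "auto"), ("DCC", "cross"), ("DACC", "acc")):
        _register(_make_cov(nm, Alphabet.RNA, 2, eng))
    _register(
        _make_pseudo(
            "PC-PseDNC-General", Alphabet.RNA, 2, 2, "parallel", (), True,
            "general parallel-correlation pseudo dinucleotide composition (RNA)",
        )
    )
    _register(
        _make_pseudo(
            "SC-PseDNC-General", Alphabet.RNA, 2, 2, "series", (), True,
            "general series-correlation pseudo dinucleotide composition (RNA)",
        )
    )
    # --- protein: 8 modes
    _register(_make_kmer(Alphabet.PROTEIN))
    for nm, eng in (("AC", "auto"), ("CC", "cross"), ("ACC", "acc")):
        _register(_make_cov(nm, Alphabet.PROTEIN, 1, eng))
    _register(
        _make_pseudo(
            "PC-PseAAC", Alphabet.PROTEIN, 1, 1, "parallel", _PSEAAC_3, False,
            "classic parallel-correlation pseudo amino acid composition",
        )
    )
    _register(
        _make_pseudo(
            "SC-PseAAC", Alphabet.PROTEIN, 1, 1, "series", _PSEAAC_2, False,
            "classic series-correlation pseudo amino acid composition",
        )
    )
    _register(
        _make_pseudo(
            "PC-PseAAC-General", Alphabet.PROTEIN, 1, 1, "parallel", _PSEAAC_3, False,
            "general parallel-correlation pseudo amino acid composition "
            "(any built-in or user-defined property set)",
        )
    )
    _register(
        _make_pseudo(
            "SC-PseAAC-General", Alphabet.PROTEIN, 1, 1, "series", _PSEAAC_2, False,
            "general series-correlation pseudo amino acid composition "
            "(any built-in or user-defined property set)",
        )
    )
    counts = {a: sum(1 for k in _REGISTRY if k[0] is a) for a in Alphabet}
    assert len(_REGISTRY) == 28, len(_REGISTRY)
    assert counts[Alphabet.DNA] == 14 and counts[Alphabet.RNA] == 6
    assert counts[Alphabet.PROTEIN] == 8


_build_registry()


def list_modes(alphabet: Alphabet | None = None) -> list[ModeSpec]:
    """All registered modes, optionally filtered by alphabet, in table order."""
    return [s for (a, _), s in _REGISTRY.items() if alphabet is None or a is alphabet]


def get_mode(name: str, alphabet: Alphabet) -> ModeSpec:
    try:
        return _REGISTRY[(alphabet, name)]
    except KeyError:
        valid = sorted({n for (a, n) in _REGISTRY if a is alphabet})
        raise UnknownModeError(
            f"unknown {alphabet.value} mode {name!r}; valid modes: {', '.join(valid)}"
        ) from None


DEFAULT_WEIGHT = 0.05
DEFAULT_PSEKNC_K = 3


def _validate_params(
    spec: ModeSpec, params: ParameterSet, allow_unsafe_k: bool
) -> ParameterSet:
    p = params
    if spec.uses_k:
        k = p.k if p.k is not None else (DEFAULT_PSEKNC_K if spec.category == "pseudo" else None)
        if k is None:
            raise ValueError(f"mode {spec.name}: parameter k is required")
        cap = _k_cap(spec.alphabet)
        if k < 1:
            raise ValueError(f"mode {spec.name}: k must be >= 1, got {k}")
        if k > cap and not allow_unsafe_k:
            raise ValueError(
                f"mode {spec.name}: k={k} exceeds the default cap of {cap} for "
                f"{spec.alphabet.value}; pass allow_unsafe_k=True (CLI --unsafe-k) "
                f"to compute large composition spaces"
            )
        p = ParameterSet(k=k, lag=p.lag, lamada=p.lamada, weight=p.weight,
                         properties=p.properties)
    if spec.uses_lag:
        if p.lag is None:
            raise ValueError(f"mode {spec.name}: parameter lag is required")
        if p.lag < 1:
            raise ValueError(f"mode {spec.name}: lag must be >= 1, got {p.lag}")
    if spec.uses_lambda:
        if p.lamada is None:
            raise ValueError(
                f"mode {spec.name}: parameter lambda is required (its legal range "
                f"depends on sequence length, so there is no silent default)"
            )
        if p.lamada < 0:
            raise ValueError(f"mode {spec.name}: lambda must be >= 0, got {p.lamada}")
        w = p.weight if p.weight is not None else DEFAULT_WEIGHT
        if w < 0:
            raise ValueError(f"mode {spec.name}: weight must be >= 0, got {w}")
        p = ParameterSet(k=p.k, lag=p.lag, lamada=p.lamada, weight=w,
                         properties=p.properties)
    return p


def _resolve_mode_props(
    spec: ModeSpec,
    params: ParameterSet,
    user_indices: Iterable[PropertyIndex],
) -> list[PropertyIndex]:
    if spec.corr_g is None:
        return []
    if spec.uses_lambda and params.lamada == 0:
        return []  # bare composition: no correlation track needed
    names = tuple(params.properties) or spec.default_props
    if not names:
        raise ValueError(
            f"mode {spec.name}: an explicit physicochemical property selection is "
            f"required (no canonical default exists for this mode)"
        )
    props = resolve_properties(names, spec.alphabet, spec.corr_g, user_indices)
    if spec.name in ("DCC", "DACC", "TCC", "TACC", "CC", "ACC") and len(props) < 2:
        raise ValueError(f"mode {spec.name}: at least 2 properties are required")
    return props


def run_mode(
    mode: str,
    seqs: list[Sequence],
    params: ParameterSet,
    alphabet: Alphabet | None = None,
    user_indices: Iterable[PropertyIndex] = (),
    allow_unsafe_k: bool = False,
) -> list[FeatureVector]:
    """Run one mode over a batch of validated sequences.

    Returns one :class:`FeatureVector` per sequence, all with identical
    labels and dimension.  Deterministic; all-or-nothing on error (the
    failing sequence id is named and nothing is returned).
    """
    if not seqs:
        return []
    if alphabet is None:
        alphabet = seqs[0].alphabet
    if alphabet is None:
        raise ValueError("sequences must have a declared alphabet (validate_alphabet)")
    for s in seqs:
        if s.alphabet is not alphabet:
            raise ValueError(
                f"sequence {s.id!r} alphabet {s.alphabet} does not match batch "
                f"alphabet {alphabet.value}"
            )
    spec = get_mode(mode, alphabet)
    p = _validate_params(spec, params, allow_unsafe_k)
    props = _resolve_mode_props(spec, p, user_indices)
    out = [spec.run(s, p, props) for s in seqs]
    ref = out[0].labels
    for v in out[1:]:
        assert v.labels == ref
    return out
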