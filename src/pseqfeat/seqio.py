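"""Typed sequences, feature vectors and FASTA input.

A :class:`Sequence` is an identifier plus a residue string ``R_1 .. R_L``
over a declared alphabet (DNA, RNA or protein).  Parsing and alphabet
validation are deliberately separate steps: :func:`read_fasta` accepts any
well-formed FASTA text, and :func:`validate_alphabet` either declares the
alphabet or fails with the exact sequence id, position and offending
character.  Ambiguity codes (N, gaps, B/J/O/U/X/Z for protein) are rejected
rather than skipped, because every downstream feature indexes exact
oligomers — a single unresolvable position would silently poison every
k-mer and correlation window that contains it.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser


class Alphabet(enum.Enum):
    """Residue alphabet of a biological sequence."""

    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"

    @property
    def letters(self) -> str:
        """Canonical letter ordering (lexicographic) for this alphabet."""
        return _LETTERS[self]

    @property
    def size(self) -> int:
        return len(_LETTERS[self])


_LETTERS: dict[Alphabet, str] = {
    Alphabet.DNA: "ACGT",
    Alphabet.RNA: "ACGU",
    Alphabet.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. record body before any header)."""


class AlphabetError(ValueError):
    """A residue is not legal for the declared alphabet."""

    def __init__(self, seq_id: str, position: int, char: str, alphabet: Alphabet):
        self.seq_id = seq_id
        self.position = position
        self.char = char
        self.alphabet = alphabet
        super().__init__(
            f"sequence {seq_id!r}: illegal {alphabet.value} residue "
            f"{char!r} at position {position}"
        )


@dataclass(frozen=True)
class Sequence:
    """An identified residue string, optionally with a declared alphabet.

    ``id`` is the token before the first whitespace of the FASTA header;
    the remainder of the header, if any, is kept in ``description``.
    """

    id: str
    residues: str
    alphabet: Alphabet | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty (L >= 1 required)")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric features with aligned labels, tagged with provenance.

    ``values`` and ``labels`` always have equal length, and every value is
    a finite real number.
    """

    mode: str
    params: Mapping[str, object]
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"label/value length mismatch: {len(self.labels)} labels, "
                f"{self.values.shape[0]} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite value in {self.mode} feature vector")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ParameterSet:
    """Parameter assignment for a feature mode.

    Only the fields relevant to the chosen mode need be set; validation is
    performed per mode by the registry.  ``lamada`` is the highest
    correlation tier λ; ``weight`` is the pseudo-component mixing weight w.
    """

    k: int | None = None
    lag: int | None = None
    lamada: int | None = None
    weight: float | None = None
    properties: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {}
        for name in ("k", "lag", "lamada", "weight"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        if self.properties:
            out["properties"] = tuple(self.properties)
        return out


_WS_RE = re.compile(r"[\s\r]+")


def read_fasta(stream: TextIO | str) -> list[Sequence]:
    """Parse multi-record FASTA text into undeclared :class:`Sequence` s.

    Residues are uppercased and internal whitespace / carriage returns are
    stripped; arbitrary line wrapping is supported.  An empty stream yields
    an empty list.  Sequence body text appearing before any ``>`` header
    raises :class:`FastaParseError` naming the line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    # Locate body-before-header ourselves so the error can name the line.
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"line {lineno}: sequence data before any '>' header"
            )
        break
    records: list[Sequence] = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        if not parts:
            raise FastaParseError("FASTA record with empty header line")
        seq_id = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        residues = _WS_RE.sub("", seq).upper()
        if not residues:
            raise FastaParseError(f"record {seq_id!r} has an empty sequence body")
        records.append(Sequence(id=seq_id, residues=residues, description=desc))
    return records


def validate_alphabet(seq: Sequence, alphabet: Alphabet) -> Sequence:
    """Return ``seq`` with ``alphabet`` declared, or raise :class:`AlphabetError`.

    Every residue must be a member of the declared alphabet; the first
    violation is reported with its 1-based position.
    """
    legal = set(alphabet.letters)
    for pos, ch in enumerate(seq.residues, start=1):
        if ch not in legal:
            raise AlphabetError(seq.id, pos, ch, alphabet)
    return replace(seq, alphabet=alphabet)


def write_fasta(seqs: Iterable[Sequence], stream: TextIO | None = None, width: int = 70) -> str:
    """Serialize sequences back to FASTA; returns the text written."""
    out = io.StringIO()
    for s in seqs:
        header = s.id if not s.description else f"{s.id} {s.description}"
        out.write(f">{header}\n")
        for i in range(0, len(s.residues), width):
            out.write(s.residues[i : i + width] + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
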