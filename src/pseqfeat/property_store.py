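"""Physicochemical index tables: built-ins, standardization, user files.

A :class:`PropertyIndex` maps every oligomer of a fixed length over an
alphabet (16 dinucleotides, 64 trinucleotides, or the 20 amino acids) to a
raw numeric value — e.g. helical twist per dinucleotide step, or residue
hydrophobicity.  Before entering any correlation formula an index is
standardized to zero mean and unit *population* variance over the complete
oligomer set (:func:`normalize_index`), so magnitudes are comparable
across properties.

Built-in tables
---------------
Four slots are packaged, sized to the canonical suite of this feature
family: 148 DNA dinucleotide, 12 DNA trinucleotide, 22 RNA dinucleotide
and 547 amino-acid indices.  The subsets whose published values are
universally reproduced ship as plain-text tables: the six local DNA
structural properties (Twist, Tilt, Roll, Shift, Slide, Rise — the PseDNC
defaults) and the three classic PseAAC amino-acid properties
(hydrophobicity, hydrophilicity, side-chain mass).  The remaining slots
are filled with deterministic SYNTHETIC indices (names prefixed
``SYNTH-``): reproducible stand-ins that exercise every formula path and
keep the catalogue at its documented size, but carry no physical meaning.
Real analyses of those slots should supply user-defined index files.

User-defined index file format (tab- or comma-delimited)::

    oligomer  AA   AC   ...  TT
    MyProp    1.0  2.0  ...  0.5

First row: the complete oligomer set in lexicographic order (an optional
leading ``oligomer`` header cell is accepted); each later row: a property
name followed by one value per oligomer.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, TextIO

import numpy as np

from .seqio import Alphabet

__all__ = [
    "PropertyIndex",
    "NormalizedIndex",
    "load_builtin",
    "normalize_index",
    "parse_user_index",
    "write_user_index",
    "oligomers",
    "resolve_properties",
    "DegeneratePropertyError",
    "IndexParseError",
    "UnknownPropertyError",
    "BUILTIN_SLOTS",
]

#: (alphabet, oligomer length) -> number of packaged built-in indices
BUILTIN_SLOTS: dict[tuple[Alphabet, int], int] = {
    (Alphabet.DNA, 2): 148,
    (Alphabet.DNA, 3): 12,
    (Alphabet.RNA, 2): 22,
    (Alphabet.PROTEIN, 1): 547,
}


class DegeneratePropertyError(ValueError):
    """Raised when an index is constant (zero variance): it cannot be standardized."""


class IndexParseError(ValueError):
    """Malformed user-defined index file; message carries row/column coordinates."""


class UnknownPropertyError(KeyError):
    """Requested property name not in the catalogue; message lists near-matches."""


def oligomers(alphabet: Alphabet, oligo_len: int) -> tuple[str, ...]:
    """The complete oligomer set of a given length, in lexicographic order."""
    if oligo_len < 1:
        raise ValueError("oligomer length must be >= 1")
    return tuple(
        "".join(p) for p in itertools.product(alphabet.letters, repeat=oligo_len)
    )


@dataclass(frozen=True)
class PropertyIndex:
    """A named physicochemical index: one raw value per oligomer."""

    name: str
    alphabet: Alphabet
    oligo_len: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = oligomers(self.alphabet, self.oligo_len)
        missing = [o for o in expected if o not in self.values]
        if missing:
            raise ValueError(
                f"index {self.name!r} incomplete: missing {missing[:4]}"
                + ("..." if len(missing) > 4 else "")
            )
        extra = set(self.values) - set(expected)
        if extra:
            raise ValueError(f"index {self.name!r} has foreign oligomers: {sorted(extra)[:4]}")
        arr = self.array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"index {self.name!r} contains non-finite values")

    def array(self) -> np.ndarray:
        """Values ordered by the lexicographic oligomer set."""
        return np.array(
            [self.values[o] for o in oligomers(self.alphabet, self.oligo_len)],
            dtype=float,
        )


@dataclass(frozen=True)
class NormalizedIndex(PropertyIndex):
    """A :class:`PropertyIndex` standardized to mean 0 / population SD 1."""

    source: PropertyIndex | None = None


def normalize_index(p: PropertyIndex) -> NormalizedIndex:
    """Standardize ``p`` to zero mean and unit population SD (divide by N).

    The oligomer set is the full population, not a sample, hence the
    population convention.  Idempotent on already-standardized indices;
    a constant index raises :class:`DegeneratePropertyError`.
    """
    if isinstance(p, NormalizedIndex):
        return p
    arr = p.array()
    sd = arr.std()  # population SD (ddof=0)
    if sd == 0.0:
        raise DegeneratePropertyError(
            f"index {p.name!r} is constant (SD = 0); cannot standardize"
        )
    z = (arr - arr.mean()) / sd
    oset = oligomers(p.alphabet, p.oligo_len)
    return NormalizedIndex(
        name=p.name,
        alphabet=p.alphabet,
        oligo_len=p.oligo_len,
        values=dict(zip(oset, z.tolist())),
        source=p,
    )


# ---------------------------------------------------------------------------
# built-in tables


def _read_table(text: str, alphabet: Alphabet, oligo_len: int) -> list[PropertyIndex]:
    return parse_user_index(io.StringIO(text), alphabet, oligo_len)


def _packaged(fname: str, alphabet: Alphabet, oligo_len: int) -> list[PropertyIndex]:
    text = resources.files("pseqfeat.data").joinpath(fname).read_text()
    return _read_table(text, alphabet, oligo_len)


def _synthetic_indices(
    alphabet: Alphabet, oligo_len: int, count: int, seed: int
) -> list[PropertyIndex]:
    """Deterministic synthetic filler indices (SYNTH-* names).

    Standard-normal draws from a fixed-seed generator; reproducible across
    runs and platforms.  They are placeholders with no physical meaning.
    """
    rng = np.random.default_rng(seed)
    oset = oligomers(alphabet, oligo_len)
    tag = f"{alphabet.value}-{oligo_len}"
    out = []
    for i in range(count):
        vals = rng.standard_normal(len(oset))
        out.append(
            PropertyIndex(
                name=f"SYNTH-{tag}-{i + 1:03d}",
                alphabet=alphabet,
                oligo_len=oligo_len,
                values=dict(zip(oset, vals.tolist())),
            )
        )
    return out


_SYNTH_SEEDS = {
    (Alphabet.DNA, 2): 101,
    (Alphabet.DNA, 3): 103,
    (Alphabet.RNA, 2): 107,
    (Alphabet.PROTEIN, 1): 109,
}

_builtin_cache: dict[tuple[Alphabet, int], list[PropertyIndex]] = {}


def load_builtin(alphabet: Alphabet, oligo_len: int) -> list[PropertyIndex]:
    """The full packaged catalogue for one (alphabet, oligomer length) slot.

    Supported slots: (DNA, 2) -> 148 indices, (DNA, 3) -> 12,
    (RNA, 2) -> 22, (PROTEIN, 1) -> 547.  Names are unique and the order
    is stable across runs: curated tables first, synthetic filler after.
    """
    slot = (alphabet, oligo_len)
    if slot not in BUILTIN_SLOTS:
        raise ValueError(
            f"no built-in indices for ({alphabet.value}, oligomer length {oligo_len}); "
            f"supported: DNA/2, DNA/3, RNA/2, PROTEIN/1"
        )
    if slot in _builtin_cache:
        return list(_builtin_cache[slot])
    curated: list[PropertyIndex] = []
    if slot == (Alphabet.DNA, 2):
        curated = _packaged("dna_dinucleotide_structural.tsv", *slot)
    elif slot == (Alphabet.PROTEIN, 1):
        curated = _packaged("protein_core.tsv", *slot)
    total = BUILTIN_SLOTS[slot]
    filler = _synthetic_indices(alphabet, oligo_len, total - len(curated), _SYNTH_SEEDS[slot])
    table = curated + filler
    names = [p.name for p in table]
    assert len(names) == len(set(names)) == total
    _builtin_cache[slot] = table
    return list(table)


# ---------------------------------------------------------------------------
# user-defined index files


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def parse_user_index(
    stream: TextIO | str, alphabet: Alphabet, oligo_len: int
) -> list[PropertyIndex]:
    """Parse a user-defined index file into :class:`PropertyIndex` objects.

    See the module docstring for the format.  Completeness is validated
    against the full oligomer set; errors carry row/column coordinates.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\r\n") for ln in stream if ln.strip()]
    if not lines:
        raise IndexParseError("empty index file")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    if header and header[0].lower() in ("oligomer", "oligo", "name", "property", ""):
        header = header[1:]
    expected = list(oligomers(alphabet, oligo_len))
    if header != expected:
        raise IndexParseError(
            f"row 1: header must list the {len(expected)} {alphabet.value} "
            f"{oligo_len}-mers in lexicographic order "
            f"(expected starts {expected[:3]}, got {header[:3]})"
        )
    out: list[PropertyIndex] = []
    seen: set[str] = set()
    for rowno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delim)]
        name, vals = cells[0], cells[1:]
        if not name:
            raise IndexParseError(f"row {rowno}: missing property name")
        if name in seen:
            raise IndexParseError(f"row {rowno}: duplicate property name {name!r}")
        if len(vals) != len(expected):
            raise IndexParseError(
                f"row {rowno} ({name!r}): expected {len(expected)} values, got {len(vals)}"
            )
        numeric: dict[str, float] = {}
        for col, (olig, cell) in enumerate(zip(expected, vals), start=2):
            try:
                numeric[olig] = float(cell)
            except ValueError:
                raise IndexParseError(
                    f"row {rowno}, column {col}: non-numeric cell {cell!r}"
                ) from None
        seen.add(name)
        out.append(
            PropertyIndex(name=name, alphabet=alphabet, oligo_len=oligo_len, values=numeric)
        )
    return out


def write_user_index(
    indices: Iterable[PropertyIndex], precision: int = 8, delimiter: str = "\t"
) -> str:
    """Serialize indices in the user-defined file format (round-trippable)."""
    indices = list(indices)
    if not indices:
        raise ValueError("nothing to write")
    a, g = indices[0].alphabet, indices[0].oligo_len
    oset = oligomers(a, g)
    rows = ["oligomer" + delimiter + delimiter.join(oset)]
    for p in indices:
        if (p.alphabet, p.oligo_len) != (a, g):
            raise ValueError("mixed alphabets/oligomer lengths in one file")
        rows.append(
            p.name + delimiter + delimiter.join(f"{p.values[o]:.{precision}g}" for o in oset)
        )
    return "\n".join(rows) + "\n"


def resolve_properties(
    names: Iterable[str],
    alphabet: Alphabet,
    oligo_len: int,
    user_indices: Iterable[PropertyIndex] = (),
) -> list[PropertyIndex]:
    """Resolve property names against user-supplied then built-in catalogues.

    Unknown names fail fast with near-matches (case-insensitive prefix /
    substring candidates) in the error message.
    """
    catalogue: dict[str, PropertyIndex] = {}
    for p in load_builtin(alphabet, oligo_len):
        catalogue[p.name] = p
    for p in user_indices:
        if (p.alphabet, p.oligo_len) != (alphabet, oligo_len):
            raise ValueError(
                f"user index {p.name!r} is {p.alphabet.value}/{p.oligo_len}-mer, "
                f"need {alphabet.value}/{oligo_len}-mer"
            )
        catalogue[p.name] = p  # user definitions shadow built-ins
    out = []
    for name in names:
        if name not in catalogue:
            low = name.lower()
            near = [n for n in catalogue if low in n.lower() or n.lower() in low][:5]
            raise UnknownPropertyError(
                f"unknown property {name!r} for {alphabet.value}/{oligo_len}-mers"
                + (f"; did you mean one of {near}?" if near else "")
            )
        out.append(catalogue[name])
    return out
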