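"""Feature-vector serialization: LIBSVM, CSV/TSV, and heat-map matrices.

Numeric output uses 8 significant digits by default — below formula
tolerance, above float noise — configurable per call.  The heat map is
exported as data only (a padded row-major grid plus a cell -> label map);
rendering belongs to downstream plotting tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

from .seqio import FeatureVector

__all__ = ["write_libsvm", "write_delimited", "heatmap_matrix", "HeatmapGrid"]

DEFAULT_PRECISION = 8


def _fmt(x: float, precision: int) -> str:
    return f"{x:.{precision}g}"


def _labels_for(vectors: Seq[FeatureVector], labels: Seq[str] | None) -> list[str]:
    if labels is None:
        return ["+1"] * len(vectors)
    if len(labels) != len(vectors):
        raise ValueError(f"{len(labels)} labels for {len(vectors)} vectors")
    return list(labels)


def write_libsvm(
    vectors: Seq[FeatureVector],
    labels: Seq[str] | None = None,
    precision: int = DEFAULT_PRECISION,
) -> str:
    """Sparse LIBSVM lines: ``label index:value ...`` with 1-based indices.

    Zero-valued features are omitted (an all-zero vector yields a bare
    label line).  The default class label is ``+1``.
    """
    labs = _labels_for(vectors, labels)
    lines = []
    for lab, vec in zip(labs, vectors):
        if any(ch.isspace() for ch in lab):
            raise ValueError(f"LIBSVM label may not contain whitespace: {lab!r}")
        pairs = [
            f"{i + 1}:{_fmt(v, precision)}"
            for i, v in enumerate(vec.values)
            if v != 0.0
        ]
        lines.append(" ".join([lab] + pairs))
    return "\n".join(lines) + "\n"


def _csv_quote(cell: str) -> str:
    if any(c in cell for c in (",", '"', "\n")):
        return '"' + cell.replace('"', '""') + '"'
    return cell


def write_delimited(
    vectors: Seq[FeatureVector],
    labels: Seq[str] | None = None,
    delimiter: str = ",",
    precision: int = DEFAULT_PRECISION,
    ids: Seq[str] | None = None,
) -> str:
    """Dense table: header row of feature labels, one data row per vector.

    ``delimiter`` is ``","`` (CSV, RFC-4180-style quoting) or ``"\\t"``
    (plain TSV; a tab inside a label is an error).  The first column holds
    the row id (sequence id when provided, else ``seq<n>``), the second the
    class label.
    """
    if delimiter not in (",", "\t"):
        raise ValueError("delimiter must be ',' or '\\t'")
    if not vectors:
        raise ValueError("nothing to write")
    ref = vectors[0].labels
    for v in vectors[1:]:
        if v.labels != ref:
            raise ValueError("vectors with differing feature labels in one table")
    labs = _labels_for(vectors, labels)
    row_ids = list(ids) if ids is not None else [f"seq{i + 1}" for i in range(len(vectors))]

    def cell(c: str) -> str:
        if delimiter == ",":
            return _csv_quote(c)
        if "\t" in c:
            raise ValueError(f"tab inside label {c!r} cannot be TSV-escaped")
        return c

    lines = [delimiter.join([cell("id"), cell("label")] + [cell(c) for c in ref])]
    for rid, lab, vec in zip(row_ids, labs, vectors):
        lines.append(
            delimiter.join(
                [cell(rid), cell(lab)] + [_fmt(v, precision) for v in vec.values]
            )
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class HeatmapGrid:
    """Row-major grid of a feature vector with an aligned label grid.

    Cells past the vector's end are padded with NaN (values) / None
    (labels).  ``grid[r, c]`` maps to feature index ``r * ncols + c``.
    """

    values: np.ndarray  # (nrows, ncols), NaN-padded
    labels: tuple[tuple[str | None, ...], ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def heatmap_matrix(vector: FeatureVector, ncols: int) -> HeatmapGrid:
    """Lay the vector out row-major into ``ceil(len/ncols)`` rows of ``ncols``."""
    if ncols < 1:
        raise ValueError(f"ncols must be >= 1, got {ncols}")
    n = len(vector)
    nrows = math.ceil(n / ncols)
    padded = np.full(nrows * ncols, np.nan)
    padded[:n] = vector.values
    label_rows = []
    flat_labels = list(vector.labels) + [None] * (nrows * ncols - n)
    for r in range(nrows):
        label_rows.append(tuple(flat_labels[r * ncols : (r + 1) * ncols]))
    return HeatmapGrid(values=padded.reshape(nrows, ncols), labels=tuple(label_rows))
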