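"""Expression-matrix I/O, normalization, and series assembly.

The forecasting pipeline works on a single 1-D signal built by
concatenating the (normalized) trajectories of every gene in a
gene x time expression matrix.  This module owns the matrix container,
the invertible normalization transforms, and the assemble/disassemble
pair that maps between matrix cells and signal positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("multilstm")

__all__ = [
    "ExpressionMatrix",
    "NormalizationRecord",
    "Signal",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize",
    "denormalize",
    "assemble_series",
    "disassemble_predictions",
]


@dataclass
class ExpressionMatrix:
    """Gene x time grid of non-negative expression values (FPKM-like).

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    time_labels
        Ordered time-point labels (opaque strings, e.g. ``"0.1h"``).
    values
        ``(G, T)`` array of finite values.
    """

    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x time array")
        if self.values.shape != (len(self.gene_ids), len(self.time_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.time_labels)} time points"
            )
        if not np.all(np.isfinite(self.values)):
            g, t = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"time {self.time_labels[t]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id {dup!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_labels)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.time_labels), self.values.copy()
        )


@dataclass
class NormalizationRecord:
    """Per-series parameters sufficient to invert a normalization.

    ``method`` is ``"minmax"`` or ``"zscore"``; ``scope`` is ``"per_gene"``
    or ``"global"``.  For minmax, ``a``/``b`` hold the series minima and
    maxima; for zscore, the means and standard deviations.  A constant
    series under minmax maps to all zeros (``b - a == 0`` flags it) and
    inverts back to the recorded constant.
    """

    method: str
    scope: str
    a: np.ndarray  # min or mean, one entry per scoped series
    b: np.ndarray  # max or sd

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "scope": self.scope,
                "a": self.a.tolist(),
                "b": self.b.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationRecord":
        d = json.loads(text)
        return cls(d["method"], d["scope"], np.asarray(d["a"]), np.asarray(d["b"]))


@dataclass
class Signal:
    """A 1-D series assembled from matrix cells.

    ``provenance`` maps each signal position to its ``(gene, time)``
    index pair; it is a bijection onto the matrix cells when the signal
    covers a full matrix.
    """

    x: np.ndarray
    ordering: str = "gene_major"
    provenance: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.provenance is not None and len(self.provenance) != self.x.size:
            raise ValueError("provenance length does not match signal length")

    def __len__(self) -> int:
        return self.x.size


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited gene x time table (first column gene ids).

    Raises ``ValueError`` naming the offending cell for missing or
    non-numeric entries and for duplicate gene ids.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene-id column plus >=1 time column")
    gene_ids = df.iloc[:, 0].tolist()
    time_labels = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                raise ValueError(
                    f"missing value at gene {gene_ids[i]!r}, column {col!r}"
                )
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {cell!r} at gene {gene_ids[i]!r}, "
                    f"column {col!r}"
                ) from None
    return ExpressionMatrix(gene_ids, time_labels, values)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix in the same dialect the reader consumes."""
    df = pd.DataFrame(matrix.values, columns=matrix.time_labels)
    df.insert(0, "gene", matrix.gene_ids)
    df.to_csv(path, sep=delimiter, index=False)


def _scoped_series(values: np.ndarray, scope: str) -> np.ndarray:
    if scope == "per_gene":
        return values  # one series per row
    if scope == "global":
        return values.reshape(1, -1)
    raise ValueError(f"unknown scope {scope!r}")


def normalize(
    matrix: ExpressionMatrix, method: str = "minmax", scope: str = "per_gene"
) -> tuple[ExpressionMatrix, NormalizationRecord]:
    """Normalize expression values for modeling.

    minmax maps each scoped series onto [0, 1] (constant series map to
    zeros, with a warning); zscore maps to mean 0, sd 1 (constant series
    map to zeros as well).  The returned record inverts the transform via
    :func:`denormalize`.
    """
    series = _scoped_series(matrix.values, scope)
    if method == "minmax":
        a = series.min(axis=1)
        b = series.max(axis=1)
        span = b - a
        degenerate = span == 0
        if np.any(degenerate):
            logger.warning(
                "minmax normalization: %d constant series mapped to zeros",
                int(degenerate.sum()),
            )
        safe = np.where(degenerate, 1.0, span)
        out = (series - a[:, None]) / safe[:, None]
    elif method == "zscore":
        a = series.mean(axis=1)
        b = series.std(axis=1, ddof=0)
        degenerate = b == 0
        safe = np.where(degenerate, 1.0, b)
        out = (series - a[:, None]) / safe[:, None]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    record = NormalizationRecord(method, scope, a.copy(), b.copy())
    normalized = ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.time_labels),
        out.reshape(matrix.values.shape),
    )
    return normalized, record


def denormalize(values: np.ndarray, record: NormalizationRecord, shape: tuple[int, int]) -> np.ndarray:
    """Invert :func:`normalize` on a (G, T)-shaped array of values."""
    values = np.asarray(values, dtype=float).reshape(shape)
    series = _scoped_series(values, record.scope)
    a, b = record.a, record.b
    if record.method == "minmax":
        span = b - a
        out = series * np.where(span == 0, 0.0, span)[:, None] + a[:, None]
    elif record.method == "zscore":
        out = series * np.where(b == 0, 0.0, b)[:, None] + a[:, None]
    else:
        raise ValueError(f"unknown normalization method {record.method!r}")
    return out.reshape(shape)


def apply_normalization(values: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Apply a previously fitted normalization to new (G, T') values."""
    values = np.asarray(values, dtype=float)
    series = _scoped_series(values, record.scope)
    a, b = record.a, record.b
    if record.method == "minmax":
        span = b - a
        out = (series - a[:, None]) / np.where(span == 0, 1.0, span)[:, None]
    elif record.method == "zscore":
        out = (series - a[:, None]) / np.where(b == 0, 1.0, b)[:, None]
    else:
        raise ValueError(f"unknown normalization method {record.method!r}")
    return out.reshape(values.shape)


def assemble_series(matrix: ExpressionMatrix, ordering: str = "gene_major") -> Signal:
    """Concatenate matrix cells into the 1-D signal the decomposition consumes.

    gene_major keeps each gene's full trajectory contiguous
    (g1t1, g1t2, ..., g2t1, ...); time_major interleaves all genes at
    time 1, then time 2, and so on.
    """
    G, T = matrix.values.shape
    if ordering == "gene_major":
        x = matrix.values.reshape(-1)
        provenance = [(g, t) for g in range(G) for t in range(T)]
    elif ordering == "time_major":
        x = matrix.values.T.reshape(-1)
        provenance = [(g, t) for t in range(T) for g in range(G)]
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    return Signal(x.copy(), ordering=ordering, provenance=provenance)


def disassemble_predictions(
    signal_values: np.ndarray,
    provenance: list[tuple[int, int]],
    record: NormalizationRecord | None,
    gene_ids: list[str],
    time_labels: list[str],
) -> ExpressionMatrix:
    """Place (optionally de-normalized) signal values back into matrix cells."""
    signal_values = np.asarray(signal_values, dtype=float).ravel()
    if provenance is None or len(provenance) == 0:
        raise ValueError("provenance required to disassemble a signal")
    if len(provenance) != signal_values.size:
        raise ValueError(
            f"length mismatch: {signal_values.size} values vs "
            f"{len(provenance)} provenance entries"
        )
    G, T = len(gene_ids), len(time_labels)
    grid = np.full((G, T), np.nan)
    for value, (g, t) in zip(signal_values, provenance):
        grid[g, t] = value
    if np.any(np.isnan(grid)):
        raise ValueError("provenance does not cover every matrix cell")
    if record is not None:
        grid = denormalize(grid, record, (G, T))
    return ExpressionMatrix(list(gene_ids), list(time_labels), grid)
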