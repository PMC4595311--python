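"""Binary biclustering of presence/absence peak matrices.

A bicluster is a subset of rows x subset of columns whose cells are all 1
in the encoded matrix.  Patterns are prepared by encoding the peak matrix:
``presence`` keeps it as-is (biclusters of 1's), ``absence`` complements
it (biclusters of 0's in the original), and ``presence_absence``
concatenates the matrix with its complement so a block of 1's in the
widened matrix is a constant-in-one-direction presence/absence pattern.

Two algorithms are provided: :func:`bimax` enumerates *every*
inclusion-maximal all-1 submatrix (exact, exhaustive), while :func:`bibit`
seeds biclusters from the bitwise AND of row pairs — much faster and
returning (generally fewer) biclusters, each contained in some maximal
one.  With labelled samples, :func:`filter_class_biclusters` keeps
class-biclusters: those whose samples predominantly share one condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ParameterError
from .matching import PeakMatrix


@dataclass
class BinaryMatrix:
    """An encoded binary matrix with row/column identities and provenance."""

    row_ids: list[str]
    col_ids: list[str]
    cells: np.ndarray
    pattern: str  # presence | absence | presence_absence
    rows_are: str  # "samples" or "peaks"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.shape != (len(self.row_ids), len(self.col_ids)):
            raise ParameterError("cell shape does not match row/col ids")
        if not np.all(np.isin(self.cells, (0, 1))):
            raise ParameterError("cells must be strictly binary")
        self.cells = self.cells.astype(np.uint8)


@dataclass(frozen=True)
class Bicluster:
    """Rows x columns of all 1's in the encoded matrix."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    class_label: str | None = None
    purity: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.col_ids))


def prepare_matrix(
    matrix: PeakMatrix,
    pattern: str = "presence",
    mode: str = "rows_are_samples",
) -> BinaryMatrix:
    """Encode a binary peak matrix for biclustering.

    ``mode='rows_are_peaks'`` transposes so m/z values index the rows.
    """
    if matrix.mode != "binary":
        raise ParameterError("biclustering requires a binary peak matrix")
    if mode not in ("rows_are_samples", "rows_are_peaks"):
        raise ParameterError(f"unknown mode {mode!r}")
    cells = matrix.values.astype(np.uint8)
    sample_ids = list(matrix.sample_ids)
    mz_ids = [f"{m:.4f}" for m in matrix.mz]
    if pattern == "presence":
        col_cells, col_ids = cells, mz_ids
        note = "identity encoding (1 = peak present)"
    elif pattern == "absence":
        col_cells, col_ids = 1 - cells, mz_ids
        note = "complement encoding (1 = peak absent)"
    elif pattern == "presence_absence":
        col_cells = np.hstack([cells, 1 - cells])
        col_ids = [f"{m}:present" for m in mz_ids] + [f"{m}:absent" for m in mz_ids]
        note = "matrix concatenated with its complement (left = presence, right = absence)"
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")
    if mode == "rows_are_peaks":
        return BinaryMatrix(
            row_ids=col_ids, col_ids=sample_ids, cells=col_cells.T,
            pattern=pattern, rows_are="peaks", provenance=note + "; transposed",
        )
    return BinaryMatrix(
        row_ids=sample_ids, col_ids=col_ids, cells=col_cells,
        pattern=pattern, rows_are="samples", provenance=note,
    )


# --------------------------------------------------------------------------
# Bimax: all inclusion-maximal all-1 submatrices via closed-concept search


def _sorted_bicluster(m: BinaryMatrix, rows: np.ndarray, cols: np.ndarray) -> Bicluster:
    return Bicluster(
        tuple(m.row_ids[i] for i in np.flatnonzero(rows)),
        tuple(m.col_ids[j] for j in np.flatnonzero(cols)),
    )


def bimax(m: BinaryMatrix, min_rows: int = 2, min_cols: int = 2) -> list[Bicluster]:
    """Enumerate every inclusion-maximal all-1 submatrix with at least
    ``min_rows`` rows and ``min_cols`` columns.

    Maximal all-1 submatrices are exactly the closed row-set/column-set
    pairs of the binary relation; they are enumerated by a canonical
    close-by-one search over columns, which visits each maximal bicluster
    once without storing duplicates.  Output is deterministic, sorted by
    row-set then column-set.
    """
    if min_rows < 1 or min_cols < 1:
        raise ParameterError("minimum dimensions must be >= 1")
    cells = m.cells.astype(bool)
    n_rows, n_cols = cells.shape
    out: list[Bicluster] = []
    if n_rows == 0 or n_cols == 0 or not cells.any():
        return out
    col_rows = [cells[:, j] for j in range(n_cols)]

    def closure_cols(rows: np.ndarray) -> np.ndarray:
        # columns that are 1 in every selected row
        if not rows.any():
            return np.ones(n_cols, dtype=bool)
        return cells[rows].all(axis=0)

    def emit(rows: np.ndarray, cols: np.ndarray) -> None:
        if rows.sum() >= min_rows and cols.sum() >= min_cols:
            out.append(_sorted_bicluster(m, rows, cols))

    def recurse(cols: np.ndarray, rows: np.ndarray, start: int) -> None:
        for j in range(start, n_cols):
            if cols[j]:
                continue
            new_rows = rows & col_rows[j]
            if not new_rows.any():
                continue
            new_cols = closure_cols(new_rows)
            # canonicity: adding column j must not pull in an earlier column
            if np.any(new_cols[:j] & ~cols[:j]):
                continue
            emit(new_rows, new_cols)
            recurse(new_cols, new_rows, j + 1)

    top_rows = np.ones(n_rows, dtype=bool)
    top_cols = closure_cols(top_rows)
    emit(top_rows, top_cols)
    recurse(top_cols, top_rows, 0)
    out.sort(key=lambda b: (b.row_ids, b.col_ids))
    return out


# --------------------------------------------------------------------------
# BiBit: row-pair seeded biclusters


def bibit(m: BinaryMatrix, min_rows: int = 2, min_cols: int = 2) -> list[Bicluster]:
    """Pair-seeded biclustering of a binary matrix.

    For every pair of rows, the seed column set is their bitwise AND; when
    the seed has at least ``min_cols`` columns, the bicluster is extended
    with every row whose AND with the seed leaves it unchanged.  Duplicates
    (identical row and column sets) are removed; output ordering matches
    :func:`bimax` (row-set then column-set).
    """
    if min_rows < 2:
        raise ParameterError("BiBit needs min_rows >= 2 (pair-seeded)")
    if min_cols < 1:
        raise ParameterError("min_cols must be >= 1")
    cells = m.cells.astype(bool)
    n_rows = cells.shape[0]
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    out: list[Bicluster] = []
    for i, j in combinations(range(n_rows), 2):
        seed = cells[i] & cells[j]
        if seed.sum() < min_cols:
            continue
        rows = (cells[:, seed].all(axis=1))
        if rows.sum() < min_rows:
            continue
        key = (tuple(np.flatnonzero(rows)), tuple(np.flatnonzero(seed)))
        if key in seen:
            continue
        seen.add(key)
        out.append(_sorted_bicluster(m, rows, seed))
    out.sort(key=lambda b: (b.row_ids, b.col_ids))
    return out


def filter_class_biclusters(
    biclusters: Sequence[Bicluster],
    condition_of: Mapping[str, str],
    rows_are: str = "samples",
    min_purity: float = 1.0,
) -> list[Bicluster]:
    """Keep class-biclusters: sample-axis purity >= ``min_purity``.

    Purity is the largest label share among the bicluster's samples (rows
    or columns depending on ``rows_are``); kept biclusters are annotated
    with the majority label (ties broken lexicographically) and purity.
    """
    if rows_are not in ("samples", "peaks"):
        raise ParameterError(f"unknown row mode {rows_are!r}")
    if not 0 <= min_purity <= 1:
        raise ParameterError("min_purity must lie in [0, 1]")
    kept: list[Bicluster] = []
    for bc in biclusters:
        sample_ids = bc.row_ids if rows_are == "samples" else bc.col_ids
        labels = []
        for s in sample_ids:
            if s not in condition_of:
                raise ParameterError(f"sample {s!r} has no condition label")
            labels.append(condition_of[s])
        counts: dict[str, int] = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        majority = min(counts, key=lambda l: (-counts[l], l))
        purity = counts[majority] / len(labels)
        if purity >= min_purity:
            kept.append(
                Bicluster(bc.row_ids, bc.col_ids, class_label=majority, purity=purity)
            )
    return kept
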