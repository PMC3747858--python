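"""Similarity-matrix containers and I/O.

PFClust operates on a single object: a symmetric ``n x n`` matrix of
pairwise similarities ``s(i, j)`` with unit diagonal.  This module provides
the validated container, conversion of point clouds to similarities
(one minus normalized Euclidean distance), and dense delimited-text I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PointSet",
    "SimilarityMatrix",
    "similarity_from_points",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_points",
    "write_points",
]

#: largest |S - S.T| accepted before a matrix is rejected as asymmetric
SYMMETRY_TOL = 1e-9


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful similarity structure."""


@dataclass(frozen=True)
class PointSet:
    """A set of ``n`` points in ``d`` dimensions, optionally gold-labeled.

    Parameters
    ----------
    coordinates : (n, d) float array
        Point coordinates in arbitrary units.
    labels : (n,) array, optional
        Gold-standard group identifier per point (used only for external
        validation; never consulted by the clustering itself).
    """

    coordinates: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coordinates must be a 2-D array (n points x d dims)")
        n, d = coords.shape
        if n < 2:
            raise ValueError(f"need at least 2 points, got {n}")
        if d < 1:
            raise ValueError("points must have at least one dimension")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        object.__setattr__(self, "coordinates", coords)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,):
                raise ValueError(
                    f"labels must have exactly one entry per point "
                    f"({labels.shape[0]} labels for {n} points)"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    def subset(self, mask: np.ndarray) -> "PointSet":
        """Return the sub-PointSet selected by a boolean mask or index array."""
        labels = None if self.labels is None else self.labels[mask]
        return PointSet(self.coordinates[mask], labels)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Validated symmetric similarity matrix with element identifiers.

    Invariants enforced at construction: square, finite off-diagonal,
    symmetric to :data:`SYMMETRY_TOL` (then symmetrized as ``(S + S.T)/2``),
    entries at most 1, diagonal set to 1 by convention.  The diagonal is
    never used by any statistic downstream.
    """

    values: np.ndarray
    element_ids: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        S = np.array(self.values, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"similarity matrix must be square, got shape {S.shape}")
        n = S.shape[0]
        if n < 2:
            raise ValueError("similarity matrix needs at least 2 elements")
        if not np.all(np.isfinite(S)):
            bad = np.argwhere(~np.isfinite(S))[0]
            raise ValueError(
                f"non-finite similarity at row {bad[0]}, column {bad[1]}"
            )
        asym = np.abs(S - S.T).max()
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.abs(S - S.T).argmax(), S.shape)
            raise ValueError(
                f"matrix not symmetric: |S[{i},{j}] - S[{j},{i}]| = {asym:.3g} "
                f"exceeds tolerance {SYMMETRY_TOL:g}"
            )
        S = (S + S.T) / 2.0
        off = S[~np.eye(n, dtype=bool)]
        if off.size and off.max() > 1.0 + 1e-12:
            raise ValueError(f"similarities must be <= 1, found {off.max()}")
        np.fill_diagonal(S, 1.0)
        S.flags.writeable = False
        object.__setattr__(self, "values", S)
        if self.element_ids is None:
            ids: tuple = tuple(str(i) for i in range(n))
        else:
            ids = tuple(str(e) for e in self.element_ids)
            if len(ids) != n:
                raise ValueError(
                    f"{len(ids)} element ids for a {n}x{n} matrix"
                )
        object.__setattr__(self, "element_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: np.ndarray) -> "SimilarityMatrix":
        """Return the principal submatrix over ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        return SimilarityMatrix(
            self.values[np.ix_(idx, idx)],
            tuple(self.element_ids[i] for i in idx),
        )


def normalize_coordinates(coords: np.ndarray) -> np.ndarray:
    """Center coordinates on their centroid and scale so max norm is 1."""
    coords = np.asarray(coords, dtype=float)
    coords = coords - coords.mean(axis=0)
    max_norm = np.linalg.norm(coords, axis=1).max()
    if max_norm == 0.0:
        raise DegenerateInputError(
            "all points are identical; similarity is undefined"
        )
    return coords / max_norm


def similarity_from_points(points: PointSet) -> SimilarityMatrix:
    """Convert a point set to similarities as one minus normalized distance.

    Coordinates are translated so their centroid sits at the origin, then
    scaled so the farthest point lies exactly one unit from the origin.
    Similarity is ``s(i, j) = 1 - ||x_i - x_j||`` on the normalized
    coordinates; off-diagonal values therefore lie in ``[-1, 1]`` (the
    maximum inter-point distance after normalization is 2).

    Raises
    ------
    DegenerateInputError
        If all points coincide (the scale factor would be zero).
    """
    coords = normalize_coordinates(points.coordinates)
    S = 1.0 - squareform(pdist(coords))
    return SimilarityMatrix(S)


def read_similarity_matrix(path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a dense delimited similarity matrix.

    Accepts either a bare numeric matrix or one with a header row and a
    leading ID column (auto-detected).  Asymmetries beyond ``1e-9``, NaNs
    and non-square shapes are rejected with the offending position named.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.rstrip("\n").split(delimiter)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # a leading empty token means an unnamed index column above the IDs
    has_header = tokens[0] == "" or not all(_numeric(t) for t in tokens if t != "")
    if has_header:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        ids: Sequence | None = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        ids = None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: NaN entry at row {i}, column {j}")
    return SimilarityMatrix(values, tuple(ids) if ids is not None else None)


def write_similarity_matrix(matrix: SimilarityMatrix, path, delimiter: str = "\t") -> None:
    """Write a similarity matrix as dense delimited text.

    Emits one header row of element ids, one leading ID column, and values
    at full float precision (``repr`` round-trip exact).
    """
    if not str(path):
        raise ValueError("empty output path")
    df = pd.DataFrame(
        matrix.values, index=list(matrix.element_ids), columns=list(matrix.element_ids)
    )
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_points(path, delimiter: str = ",", labeled: bool | None = None) -> PointSet:
    """Read points from delimited text, one point per row.

    If the final column is not floating-point (group ids are integers or
    strings, coordinates are floats) it is taken as the gold-standard label
    column; pass ``labeled`` explicitly to override the heuristic.
    """
    df = pd.read_csv(path, sep=delimiter, header=None)
    last = df.iloc[:, -1]
    if labeled is None:
        labeled = not pd.api.types.is_float_dtype(last)
    if labeled:
        return PointSet(df.iloc[:, :-1].to_numpy(dtype=float), last.to_numpy())
    return PointSet(df.to_numpy(dtype=float))


def write_points(points: PointSet, path, delimiter: str = ",") -> None:
    """Write points (and labels, if present) as delimited text without header."""
    df = pd.DataFrame(points.coordinates)
    if points.labels is not None:
        df["label"] = points.labels
    df.to_csv(path, sep=delimiter, header=False, index=False)
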