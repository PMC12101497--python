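"""Functional connectomes from node time series.

Turns a node × timepoint matrix into a Fisher-z Pearson connectivity matrix
and a fixed-order edge feature vector. The edge enumeration convention —
0-based, row-major over the strict upper triangle:
(0,1), (0,2), ..., (0,n-1), (1,2), ..., (n-2,n-1) — is declared once in
:class:`EdgeIndexMap` and used by every consumer (prediction, importance,
lesioning), so an edge index means the same node pair everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ORDERING_CONVENTION = "upper-row-major-0based"

#: correlations are clipped to +/-(1 - _R_CLIP_EPS) before arctanh so that
#: duplicate node series (a data defect) do not crash batch runs
_R_CLIP_EPS = 1e-7


class DegenerateInputError(ValueError):
    """A node time series has zero variance (constant signal)."""


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between edge indices and unordered node pairs (i, j), i < j.

    Parameters
    ----------
    n_nodes
        Number of atlas nodes. A 268-node atlas yields 35,778 edges.
    """

    n_nodes: int
    ordering: str = ORDERING_CONVENTION

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"need at least 2 nodes, got {self.n_nodes}")
        if self.ordering != ORDERING_CONVENTION:
            raise ValueError(f"unsupported edge ordering {self.ordering!r}")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def __len__(self) -> int:
        return self.n_edges

    def index_of(self, i: int, j: int) -> int:
        """Edge index of the unordered pair (i, j)."""
        if i == j:
            raise ValueError("diagonal entries are not edges")
        if i > j:
            i, j = j, i
        if i < 0 or j >= self.n_nodes:
            raise ValueError(f"node pair ({i}, {j}) out of range for n={self.n_nodes}")
        n = self.n_nodes
        # edges in rows 0..i-1, then offset within row i
        return i * (n - 1) - i * (i - 1) // 2 + (j - i - 1)

    def endpoints(self, index: int) -> tuple[int, int]:
        """Node pair (i, j), i < j, for an edge index. Inverse of index_of."""
        if not 0 <= index < self.n_edges:
            raise ValueError(f"edge index {index} out of range [0, {self.n_edges})")
        i, j = self.rows[index], self.cols[index]
        return int(i), int(j)

    @property
    def rows(self) -> np.ndarray:
        return self._triu()[0]

    @property
    def cols(self) -> np.ndarray:
        return self._triu()[1]

    def _triu(self) -> tuple[np.ndarray, np.ndarray]:
        cache = _TRIU_CACHE
        if self.n_nodes not in cache:
            cache[self.n_nodes] = np.triu_indices(self.n_nodes, k=1)
        return cache[self.n_nodes]


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


@dataclass
class NodeTimeSeries:
    """Per-subject node × timepoint signal matrix, node order as in the atlas."""

    subject_id: str
    data: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D node × timepoint matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of {self.subject_id}")
        if self.node_ids is None:
            self.node_ids = np.arange(self.data.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]


@dataclass
class Connectome:
    """Symmetric Fisher-z connectivity matrix for one subject."""

    subject_id: str
    z_matrix: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if not np.allclose(z, z.T, equal_nan=True):
            raise ValueError("z_matrix must be symmetric")
        self.z_matrix = z

    @property
    def n_nodes(self) -> int:
        return self.z_matrix.shape[0]


def correlation_matrix(ts: NodeTimeSeries) -> np.ndarray:
    """Pearson correlation between every pair of node time courses.

    Raises
    ------
    DegenerateInputError
        If any node has zero variance, naming the offending node(s).
    """
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance node(s) {dead.tolist()} in subject {ts.subject_id}"
        )
    r = np.corrcoef(ts.data)
    # numerical guard: corrcoef can stray by ~1e-16
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher's z transform, z = arctanh(r).

    Correlations with |r| >= 1 (exactly duplicated or anti-correlated series)
    are clipped to +/-(1 - 1e-7) with a warning rather than erroring, so one
    defective node pair does not abort a cohort run.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) == 1):
        warnings.warn(
            "|r| = 1 encountered; clipping before Fisher z", stacklevel=2
        )
        r = np.clip(r, -1 + _R_CLIP_EPS, 1 - _R_CLIP_EPS)
    z = np.arctanh(r)
    return float(z) if scalar else z


def connectome_from_timeseries(ts: NodeTimeSeries) -> Connectome:
    """Pearson correlation matrix, Fisher-z transformed, zero diagonal."""
    r = correlation_matrix(ts)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    z[off] = fisher_z(r[off])
    return Connectome(subject_id=ts.subject_id, z_matrix=z)


def vectorize_upper(c: Connectome | np.ndarray, emap: EdgeIndexMap) -> np.ndarray:
    """Flatten the strict upper triangle into the fixed-order edge vector."""
    m = c.z_matrix if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if m.shape != (emap.n_nodes, emap.n_nodes):
        raise ValueError(
            f"matrix shape {m.shape} does not match map n_nodes={emap.n_nodes}"
        )
    return m[emap.rows, emap.cols].copy()


def devectorize(vec: np.ndarray, emap: EdgeIndexMap) -> np.ndarray:
    """Rebuild the symmetric off-diagonal matrix from an edge vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (emap.n_edges,):
        raise ValueError(f"expected {emap.n_edges} edges, got {vec.shape}")
    m = np.zeros((emap.n_nodes, emap.n_nodes))
    m[emap.rows, emap.cols] = vec
    m[emap.cols, emap.rows] = vec
    return m


def edge_endpoints(index: int, emap: EdgeIndexMap) -> tuple[int, int]:
    """Node pair (i, j) of an edge index; see EdgeIndexMap.endpoints."""
    return emap.endpoints(index)


def edge_vectors_from_cohort(
    cohort: list[NodeTimeSeries], emap: EdgeIndexMap | None = None
) -> tuple[np.ndarray, list[str], EdgeIndexMap]:
    """Stack per-subject Fisher-z edge vectors into a subjects × edges matrix."""
    if not cohort:
        raise ValueError("empty cohort")
    if emap is None:
        emap = EdgeIndexMap(cohort[0].n_nodes)
    X = np.empty((len(cohort), emap.n_edges))
    ids = []
    for s, ts in enumerate(cohort):
        X[s] = vectorize_upper(connectome_from_timeseries(ts), emap)
        ids.append(ts.subject_id)
    return X, ids, emap
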