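"""Network-level importance of the predictive edges.

Aggregates the consensus edges — those selected in *every* LOOCV fold at a
threshold — into between-network connectivity strengths and per-network
relative degrees:

    Edge_IJ = sum over consensus edges (i in I, j in J) of |edge weight|
    RD_I    = sum_J binarize(Edge_IJ) / sum_I sum_J binarize(Edge_IJ)

where binarize maps any nonzero value to 1. RD sums to 1 over networks
whenever any Edge entry is nonzero. Within-network edges contribute to the
diagonal Edge_II and are counted by the double sum exactly as written; chord
displays typically hide the diagonal, which is a display choice only.

Node degree within a network counts the consensus edges incident to each
node, ranking the network's nodes by predictive involvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import EdgeIndexMap
from .prediction import FoldModel
from .synthetic_data import AtlasPartition


@dataclass
class ConsensusSet:
    """Edges selected in all LOOCV folds, with fold-summed absolute weights."""

    edge_indices: np.ndarray
    summed_abs_weights: np.ndarray

    def __post_init__(self) -> None:
        self.edge_indices = np.asarray(self.edge_indices, dtype=np.int64)
        self.summed_abs_weights = np.asarray(self.summed_abs_weights, dtype=float)
        if self.edge_indices.shape != self.summed_abs_weights.shape:
            raise ValueError("one summed weight per consensus edge required")


@dataclass
class NetworkEdgeMatrix:
    """Symmetric networks × networks matrix of summed absolute edge weights."""

    networks: tuple[str, ...]
    edge: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edge, index=self.networks, columns=self.networks)


@dataclass
class RDVector:
    """Relative degree per network; sums to 1 when any Edge is nonzero."""

    networks: tuple[str, ...]
    rd: np.ndarray
    all_zero: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(self.rd, index=self.networks, name="relative_degree")


def consensus_features(folds: list[FoldModel]) -> ConsensusSet:
    """Intersect per-fold selections; sum |weight| over all folds per edge.

    An edge missing from even one fold is excluded. An empty intersection is
    a valid (empty) consensus, reported with a warning.
    """
    if not folds:
        raise ValueError("need at least one fold")
    common = folds[0].selected_edge_indices
    for fm in folds[1:]:
        common = np.intersect1d(common, fm.selected_edge_indices, assume_unique=True)
        if common.size == 0:
            break
    if common.size == 0:
        warnings.warn("consensus set is empty: no edge selected in every fold",
                      stacklevel=2)
        return ConsensusSet(np.empty(0, dtype=np.int64), np.empty(0))
    total = np.zeros(common.size)
    for fm in folds:
        pos = np.searchsorted(fm.selected_edge_indices, common)
        total += np.abs(fm.training_weights[pos])
    return ConsensusSet(common, total)


def network_edge_matrix(
    consensus: ConsensusSet, emap: EdgeIndexMap, atlas: AtlasPartition
) -> NetworkEdgeMatrix:
    """Edge_IJ: summed |weight| of consensus edges linking networks I and J."""
    if atlas.n_nodes != emap.n_nodes:
        raise ValueError("atlas and edge map disagree on node count")
    m = atlas.n_networks
    E = np.zeros((m, m))
    if consensus.edge_indices.size:
        if consensus.edge_indices.max() >= emap.n_edges:
            raise ValueError("consensus edge index out of range for edge map")
        net = atlas.network_index()
        ni = net[emap.rows[consensus.edge_indices]]
        nj = net[emap.cols[consensus.edge_indices]]
        for a, b, w in zip(ni, nj, np.abs(consensus.summed_abs_weights)):
            E[a, b] += w
            if a != b:
                E[b, a] += w
    return NetworkEdgeMatrix(networks=atlas.network_names, edge=E)


def relative_degree(E: NetworkEdgeMatrix) -> RDVector:
    """RD_I = sum_J binarize(Edge_IJ) / sum_I sum_J binarize(Edge_IJ).

    Applied literally: an ordered double sum over the symmetric binarized
    matrix, diagonal counted once per row. An all-zero Edge matrix has no
    defined RD; returns zeros with ``all_zero=True``.
    """
    B = (E.edge != 0).astype(float)
    denom = B.sum()
    if denom == 0:
        return RDVector(networks=E.networks, rd=np.zeros(len(E.networks)),
                        all_zero=True)
    rd = B.sum(axis=1) / denom
    assert abs(rd.sum() - 1.0) < 1e-12
    return RDVector(networks=E.networks, rd=rd)


def node_degree(
    consensus: ConsensusSet,
    emap: EdgeIndexMap,
    atlas: AtlasPartition,
    network: str,
) -> pd.DataFrame:
    """Consensus-edge degree of every node in a network, ranked descending.

    Degree counts unordered consensus edges incident to the node (an edge
    wholly inside the network adds 1 to each endpoint). Ties rank by node id.
    """
    nodes = atlas.nodes_of(network)  # raises on unknown network
    deg = np.zeros(atlas.n_nodes, dtype=np.int64)
    if consensus.edge_indices.size:
        np.add.at(deg, emap.rows[consensus.edge_indices], 1)
        np.add.at(deg, emap.cols[consensus.edge_indices], 1)
    out = pd.DataFrame(
        {
            "node_id": nodes,
            "network": network,
            "degree": deg[nodes],
        }
    ).sort_values(["degree", "node_id"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
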