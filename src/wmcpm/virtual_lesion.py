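"""Virtual lesion analysis: is a network necessary for prediction?

Removing every node of one network from the feature space (keeping only
edges with *both* endpoints outside it) and re-running the full LOOCV
prediction — with per-mille feature counts recomputed on the reduced edge
total — tests whether that network is necessary for predicting a behavioral
component. Scanning all networks and BH-correcting across the scan family
(thresholds × lesioned networks) identifies networks whose removal abolishes
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import EdgeIndexMap
from .prediction import (
    PredictionConfig,
    ThresholdResult,
    _LoocvEngine,
    _attach_p,
    _observed_results,
    fdr_correct,
    permutation_null,
)
from .synthetic_data import AtlasPartition


@dataclass
class LesionOutcome:
    """Full per-threshold prediction results with one network removed."""

    lesioned_network: str
    retained_edge_indices: np.ndarray
    results: dict[int, ThresholdResult] = field(default_factory=dict)
    fdr_family_size: int = 0


def lesion_feature_space(
    emap: EdgeIndexMap, atlas: AtlasPartition, network: str
) -> np.ndarray:
    """Edge indices whose two endpoints both lie outside the lesioned network.

    Removing k of n nodes retains exactly (n-k)(n-k-1)/2 edges.
    """
    removed = atlas.nodes_of(network)  # raises on unknown network
    gone = np.zeros(atlas.n_nodes, dtype=bool)
    gone[removed] = True
    return np.flatnonzero(~gone[emap.rows] & ~gone[emap.cols])


def lesion_scan(
    X: np.ndarray,
    y: np.ndarray,
    atlas: AtlasPartition,
    emap: EdgeIndexMap,
    config: PredictionConfig | None = None,
    networks: list[str] | None = None,
    alpha: float = 0.05,
) -> list[LesionOutcome]:
    """Lesion each network in turn and re-run prediction with permutations.

    Feature counts at each per-mille threshold are recomputed from the
    reduced edge total, so selection stays proportional. BH correction runs
    over the whole scan family — |thresholds| × |networks scanned| — and
    never pools across scans.
    """
    config = config or PredictionConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    networks = list(networks) if networks is not None else list(atlas.network_names)
    outcomes = []
    family = len(networks) * len(config.per_mille_thresholds)
    for net in networks:
        keep = lesion_feature_space(emap, atlas, net)
        Xr = np.ascontiguousarray(X[:, keep])
        engine = _LoocvEngine(Xr, config)
        results = _observed_results(engine, y, config.per_mille_thresholds)
        null = permutation_null(Xr, y, config, config.per_mille_thresholds,
                                engine=engine)
        for t, res in results.items():
            _attach_p(res, null[t])
            # report selections in the original edge indexing
            res.consensus_edges = keep[res.consensus_edges]
            for fm in res.folds:
                fm.selected_edge_indices = keep[fm.selected_edge_indices]
        outcomes.append(
            LesionOutcome(
                lesioned_network=net,
                retained_edge_indices=keep,
                results=results,
                fdr_family_size=family,
            )
        )
    # BH across the full scan family
    ps, slots = [], []
    for oc in outcomes:
        for t, res in oc.results.items():
            ps.append(res.p_permutation)
            slots.append(res)
    flags, _ = fdr_correct(ps, alpha=alpha)
    for res, flag in zip(slots, flags):
        res.q_significant = bool(flag)
    return outcomes


def scan_table(outcomes: list[LesionOutcome]) -> pd.DataFrame:
    """One row per (lesioned network, threshold): r, p, FDR flag."""
    rows = []
    for oc in outcomes:
        for t, res in sorted(oc.results.items()):
            rows.append(
                {
                    "network": oc.lesioned_network,
                    "per_mille": t,
                    "n_features": res.n_features,
                    "r": res.r_observed,
                    "p": res.p_permutation,
                    "significant": res.q_significant,
                }
            )
    return pd.DataFrame(rows)
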