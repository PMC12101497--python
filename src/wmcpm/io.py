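"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain TSV (or JSON for nested results), so runs are
inspectable and diffable. Edge-vector files carry a sidecar JSON recording
the node count and the edge-ordering convention string, making the feature
order auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ORDERING_CONVENTION, EdgeIndexMap, NodeTimeSeries
from .prediction import ThresholdResult
from .synthetic_data import AtlasPartition, GroundTruth

_FLOAT_FMT = "%.10g"


# -- atlas ------------------------------------------------------------------

def write_atlas(atlas: AtlasPartition, path) -> None:
    df = pd.DataFrame(
        {"node_id": np.arange(atlas.n_nodes), "network_label": atlas.labels}
    )
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path) -> AtlasPartition:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("node_id")
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("atlas must cover node ids 0..n-1 exactly once")
    labels = df["network_label"].astype(str).to_numpy(dtype=object)
    names = tuple(dict.fromkeys(labels))  # first-appearance order
    return AtlasPartition(labels=labels, network_names=names)


# -- time series ------------------------------------------------------------

def write_timeseries_dir(cohort: list[NodeTimeSeries], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ts in cohort:
        p = outdir / f"{ts.subject_id}.tsv"
        np.savetxt(p, ts.data, fmt=_FLOAT_FMT, delimiter="\t")
        paths.append(p)
    return paths


def read_timeseries_dir(indir) -> list[NodeTimeSeries]:
    indir = Path(indir)
    out = []
    for p in sorted(indir.glob("*.tsv")):
        data = np.loadtxt(p, delimiter="\t", ndmin=2)
        out.append(NodeTimeSeries(subject_id=p.stem, data=data))
    if not out:
        raise FileNotFoundError(f"no .tsv time-series files under {indir}")
    return out


# -- behavior / composites --------------------------------------------------

def write_behavior(subject_ids, scores, path, column: str = "score") -> None:
    pd.DataFrame({"subject_id": subject_ids, column: scores}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_behavior(path, column: str = "score") -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if column not in df.columns:
        raise ValueError(f"behavior table lacks column {column!r}; has {list(df.columns)}")
    return df["subject_id"].astype(str).tolist(), df[column].to_numpy(dtype=float)


def write_composites(comps: pd.DataFrame, path) -> None:
    comps.to_csv(path, sep="\t", float_format="%.10g")


# -- edge vectors -----------------------------------------------------------

def write_edge_vectors(X, subject_ids, emap: EdgeIndexMap, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "edges_meta.json").write_text(
        json.dumps(
            {"n_nodes": emap.n_nodes, "n_edges": emap.n_edges,
             "ordering": ORDERING_CONVENTION, "subjects": list(subject_ids)},
            indent=2,
        )
    )
    for sid, row in zip(subject_ids, np.asarray(X)):
        np.savetxt(outdir / f"{sid}_edges.tsv", row[None, :], fmt=_FLOAT_FMT,
                   delimiter="\t")


def read_edge_vectors(indir) -> tuple[np.ndarray, list[str], EdgeIndexMap]:
    indir = Path(indir)
    meta = json.loads((indir / "edges_meta.json").read_text())
    if meta["ordering"] != ORDERING_CONVENTION:
        raise ValueError(f"unsupported edge ordering {meta['ordering']!r}")
    emap = EdgeIndexMap(meta["n_nodes"])
    ids = meta["subjects"]
    X = np.empty((len(ids), emap.n_edges))
    for s, sid in enumerate(ids):
        X[s] = np.loadtxt(indir / f"{sid}_edges.tsv", delimiter="\t")
    return X, ids, emap


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


# -- ROI series and events --------------------------------------------------

def read_roi_series(series_path, events_path, tr: float,
                    baseline_label: str | None = None):
    """ROI signal (one value per line) plus a 3-column events table.

    The events table is tab-delimited with header onset_s, duration_s,
    condition (the standard tabular events dialect).
    """
    from .roi_timecourse import RoiSeries

    values = np.loadtxt(series_path)
    events = pd.read_csv(events_path, sep="\t")
    needed = {"onset_s", "condition"}
    if not needed <= set(events.columns):
        raise ValueError(f"events table needs columns {sorted(needed)}")
    return RoiSeries(
        values=values,
        tr=tr,
        onsets=events["onset_s"].to_numpy(dtype=float),
        conditions=events["condition"].to_numpy(dtype=object),
        baseline_label=baseline_label,
    )


# -- prediction results -----------------------------------------------------

def results_to_json(results: dict[int, ThresholdResult]) -> str:
    payload = {}
    for t, res in sorted(results.items()):
        payload[str(t)] = {
            "per_mille": res.per_mille,
            "n_features": res.n_features,
            "r_observed": res.r_observed,
            "p_permutation": res.p_permutation,
            "p_permutation_unbiased": res.p_permutation_unbiased,
            "q_significant": res.q_significant,
            "consensus_edges": res.consensus_edges.tolist(),
            "folds": [
                {
                    "held_out_subject": fm.held_out_subject,
                    "selected_edge_indices": fm.selected_edge_indices.tolist(),
                    "training_weights": np.asarray(fm.training_weights).tolist(),
                    "prediction": fm.prediction,
                }
                for fm in res.folds
            ],
        }
    return json.dumps(payload, indent=2, sort_keys=True)


def results_summary_table(
    results_by_component: dict[str, dict[int, ThresholdResult]]
) -> pd.DataFrame:
    rows = []
    for comp, results in results_by_component.items():
        for t, res in sorted(results.items()):
            rows.append(
                {
                    "component": comp,
                    "per_mille": t,
                    "n_features": res.n_features,
                    "r": res.r_observed,
                    "p": res.p_permutation,
                    "significant": res.q_significant,
                }
            )
    return pd.DataFrame(rows)
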