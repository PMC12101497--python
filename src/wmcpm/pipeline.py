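"""End-to-end orchestration: simulate -> connect -> predict -> importance -> lesion.

A single :class:`RunConfig` drives every stage; one master seed feeds named
substreams (simulation, permutations), and a manifest JSON records inputs,
seeds, and stage outputs so any results table can be regenerated from its
manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io
from .network_importance import (
    consensus_features,
    network_edge_matrix,
    node_degree,
    relative_degree,
)
from .prediction import PredictionConfig, predict_component
from .synthetic_data import simulate_dataset
from .virtual_lesion import lesion_scan, scan_table


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # simulation scale
    n_subjects: int = 103
    n_nodes: int = 268
    network_sizes: tuple[int, ...] | None = None
    network_names: tuple[str, ...] | None = None
    n_timepoints: int = 240
    n_signal_edges: int = 30
    target_network: str = "cerebellum"
    snr: float = 1.5
    # prediction
    per_mille_thresholds: tuple[int, ...] = (1, 3, 5, 7, 9)
    n_permutations: int = 1000
    alpha: float = 0.05
    run_lesion_scan: bool = False
    component: str = "EVENT"

    def prediction_config(self, seed: int) -> PredictionConfig:
        return PredictionConfig(
            per_mille_thresholds=tuple(self.per_mille_thresholds),
            n_permutations=self.n_permutations,
            seed=seed,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "status": "running",
    }
    manifest_path = out / "manifest.json"

    def _save() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        ss = np.random.SeedSequence(config.seed)
        sim_seed, perm_seed = (int(c.generate_state(1)[0] % 2**31)
                               for c in ss.spawn(2))
        manifest["seeds"] = {"master": config.seed, "simulation": sim_seed,
                             "permutation": perm_seed}

        # --- simulate + connect -------------------------------------------
        kwargs = {}
        if config.network_sizes is not None:
            kwargs["network_sizes"] = config.network_sizes
        if config.network_names is not None:
            kwargs["network_names"] = config.network_names
        ds = simulate_dataset(
            n_subjects=config.n_subjects,
            n_nodes=config.n_nodes,
            n_timepoints=config.n_timepoints,
            n_signal_edges=config.n_signal_edges,
            target_network=config.target_network,
            snr=config.snr,
            seed=sim_seed,
            **kwargs,
        )
        io.write_atlas(ds.atlas, out / "atlas.tsv")
        io.write_behavior(ds.subject_ids, ds.y, out / "behavior.tsv")
        io.write_ground_truth(ds.truth, out / "ground_truth.json")
        io.write_edge_vectors(ds.X, ds.subject_ids, ds.emap, out / "edges")
        manifest["stages"]["simulate"] = {
            "n_subjects": config.n_subjects,
            "n_edges": int(ds.emap.n_edges),
            "outputs": ["atlas.tsv", "behavior.tsv", "ground_truth.json", "edges/"],
        }
        _save()

        # --- predict ------------------------------------------------------
        pcfg = config.prediction_config(perm_seed)
        results = predict_component(ds.X, ds.y, pcfg, alpha=config.alpha)
        (out / f"prediction_{config.component}.json").write_text(
            io.results_to_json(results)
        )
        summary = io.results_summary_table({config.component: results})
        summary.to_csv(out / "prediction_summary.tsv", sep="\t", index=False,
                       float_format="%.10g")
        manifest["stages"]["predict"] = {
            "thresholds": list(pcfg.per_mille_thresholds),
            "n_permutations": pcfg.n_permutations,
            "r_observed": {str(t): results[t].r_observed for t in results},
            "outputs": [f"prediction_{config.component}.json",
                        "prediction_summary.tsv"],
        }
        _save()

        # --- importance ---------------------------------------------------
        # RD binarizes network-pair hits, so dense consensus sets at liberal
        # thresholds saturate it; use the sparsest significant model (fall
        # back to best r when nothing is significant)
        sig = [t for t in results if results[t].q_significant]
        best_t = min(sig) if sig else max(results,
                                          key=lambda t: results[t].r_observed)
        cons = consensus_features(results[best_t].folds)
        E = network_edge_matrix(cons, ds.emap, ds.atlas)
        rd = relative_degree(E)
        E.to_frame().to_csv(out / "network_edge_matrix.tsv", sep="\t",
                            float_format="%.10g")
        rd.to_series().to_csv(out / "relative_degree.tsv", sep="\t",
                              float_format="%.10g")
        degrees = node_degree(cons, ds.emap, ds.atlas, config.target_network)
        degrees.to_csv(out / "node_degree.tsv", sep="\t", index=False)
        manifest["stages"]["importance"] = {
            "threshold_used": best_t,
            "n_consensus_edges": int(cons.edge_indices.size),
            "top_network": rd.networks[int(np.argmax(rd.rd))],
            "outputs": ["network_edge_matrix.tsv", "relative_degree.tsv",
                        "node_degree.tsv"],
        }
        _save()

        # --- lesion scan (optional) ---------------------------------------
        if config.run_lesion_scan:
            outcomes = lesion_scan(ds.X, ds.y, ds.atlas, ds.emap, pcfg,
                                   alpha=config.alpha)
            scan_table(outcomes).to_csv(out / "lesion_scan.tsv", sep="\t",
                                        index=False, float_format="%.10g")
            manifest["stages"]["lesion_scan"] = {
                "networks": [oc.lesioned_network for oc in outcomes],
                "outputs": ["lesion_scan.tsv"],
            }
            _save()

        manifest["status"] = "complete"
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        _save()
        raise
    _save()
    return manifest
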