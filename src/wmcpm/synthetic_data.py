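"""Synthetic cohorts with known ground truth.

Everything downstream — scoring, connectomes, LOOCV SVR prediction, network
importance, virtual lesions — is exercised on data generated here, where the
true signal-carrying edges, their weights, and the behavioral noise level are
known exactly. The generator emulates three things:

* multi-subject node time series with block (within-network) correlation
  structure under a stationary Gaussian model;
* a behavioral score that is a sparse linear function of connectivity edges
  confined to one designated network, plus Gaussian noise;
* change-detection trial counts under a whole-display guessing model, chosen
  because it makes the Cowan capacity estimator K = S(H - F) unbiased.

Default cohort scale mirrors the study the pipeline is designed for:
103 subjects, 268 nodes grouped into 10 networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .behavior_scoring import TrialCounts
from .connectome import EdgeIndexMap, NodeTimeSeries, edge_vectors_from_cohort


class InvalidConfigurationError(ValueError):
    """A generator was asked for an impossible or inconsistent configuration."""


#: default 10-network partition of 268 nodes; the cerebellum network is the
#: default home of the synthetic signal edges
DEFAULT_NETWORK_SIZES = (29, 34, 20, 28, 50, 18, 9, 27, 33, 20)
DEFAULT_NETWORK_NAMES = (
    "medial_frontal",
    "frontoparietal",
    "default_mode",
    "subcortical",
    "motor",
    "visual_a",
    "visual_b",
    "visual_association",
    "salience",
    "cerebellum",
)


@dataclass(frozen=True)
class AtlasPartition:
    """Assignment of every atlas node to exactly one network."""

    labels: np.ndarray  # per-node network label, length n_nodes
    network_names: tuple[str, ...]  # fixed display/order convention

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        missing = set(self.labels) - set(self.network_names)
        if missing:
            raise InvalidConfigurationError(f"labels not in network_names: {missing}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def nodes_of(self, network: str) -> np.ndarray:
        if network not in self.network_names:
            raise ValueError(f"unknown network {network!r}")
        return np.flatnonzero(self.labels == network)

    def sizes(self) -> dict[str, int]:
        return {name: int((self.labels == name).sum()) for name in self.network_names}

    def network_index(self) -> np.ndarray:
        """Per-node integer index into network_names."""
        lut = {name: k for k, name in enumerate(self.network_names)}
        return np.array([lut[lab] for lab in self.labels], dtype=np.int64)


@dataclass
class GroundTruth:
    """The planted edge-behavior association a recovery run must find."""

    signal_edge_indices: np.ndarray
    signal_weights: np.ndarray
    noise_sd: float
    target_network: str
    seed: int
    both_endpoints: bool = True

    def __post_init__(self) -> None:
        self.signal_edge_indices = np.asarray(self.signal_edge_indices, dtype=np.int64)
        self.signal_weights = np.asarray(self.signal_weights, dtype=float)
        if self.signal_edge_indices.size != np.unique(self.signal_edge_indices).size:
            raise InvalidConfigurationError("signal edge indices must be unique")
        if self.signal_edge_indices.shape != self.signal_weights.shape:
            raise InvalidConfigurationError("one weight per signal edge required")
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise_sd must be >= 0")

    def validate(self, emap: EdgeIndexMap, atlas: AtlasPartition) -> None:
        if self.signal_edge_indices.size and (
            self.signal_edge_indices.min() < 0
            or self.signal_edge_indices.max() >= emap.n_edges
        ):
            raise InvalidConfigurationError("signal edge index out of range")
        in_target = set(atlas.nodes_of(self.target_network).tolist())
        for e in self.signal_edge_indices:
            i, j = emap.endpoints(int(e))
            ok = (i in in_target and j in in_target) if self.both_endpoints else (
                i in in_target or j in in_target
            )
            if not ok:
                raise InvalidConfigurationError(
                    f"signal edge {e} ({i},{j}) not confined to {self.target_network}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "signal_edge_indices": self.signal_edge_indices.tolist(),
                "signal_weights": self.signal_weights.tolist(),
                "noise_sd": self.noise_sd,
                "target_network": self.target_network,
                "seed": self.seed,
                "both_endpoints": self.both_endpoints,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TrialGenerativeParams:
    """Generative parameters for change-detection trials.

    ``true_K`` is the number of items actually held in memory, ``S`` the set
    size, ``g`` the guess rate when the probed item is not in memory.
    """

    true_K: float
    S: int
    g: float
    n_trials_change: int
    n_trials_nochange: int

    def __post_init__(self) -> None:
        if self.true_K < 0:
            raise InvalidConfigurationError("true_K must be >= 0")
        if self.S < 1:
            raise InvalidConfigurationError("set size must be >= 1")
        if not 0 <= self.g <= 1:
            raise InvalidConfigurationError("guess rate must be in [0, 1]")
        if self.n_trials_change < 0 or self.n_trials_nochange < 0:
            raise InvalidConfigurationError("trial counts must be >= 0")


def make_atlas(
    n_nodes: int,
    network_sizes=DEFAULT_NETWORK_SIZES,
    network_names=DEFAULT_NETWORK_NAMES,
    seed: int | None = None,
) -> AtlasPartition:
    """Partition ``n_nodes`` nodes into networks of the given sizes.

    With a seed, node-to-network assignment is a seeded permutation (networks
    are interleaved through the node ordering, as in real parcellations);
    without one, networks occupy contiguous node blocks.
    """
    network_sizes = tuple(int(s) for s in network_sizes)
    network_names = tuple(network_names)
    if len(network_sizes) != len(network_names):
        raise InvalidConfigurationError(
            f"{len(network_sizes)} sizes for {len(network_names)} names"
        )
    if sum(network_sizes) != n_nodes:
        raise InvalidConfigurationError(
            f"network sizes sum to {sum(network_sizes)}, expected {n_nodes}"
        )
    labels = np.repeat(np.array(network_names, dtype=object), network_sizes)
    if seed is not None:
        perm = np.random.default_rng(seed).permutation(n_nodes)
        labels = labels[perm]
    return AtlasPartition(labels=labels, network_names=network_names)


def simulate_timeseries(
    n_subjects: int,
    atlas: AtlasPartition,
    n_timepoints: int = 240,
    rho_within: float = 0.3,
    rho_between: float = 0.0,
    seed: int = 0,
) -> list[NodeTimeSeries]:
    """Stationary Gaussian node time series with block covariance.

    Nodes in the same network correlate at ``rho_within``, across networks at
    ``rho_between``. No temporal autocorrelation: the downstream pipeline
    consumes only the static correlation matrix.
    """
    if not (-1 < rho_between <= rho_within < 1):
        raise InvalidConfigurationError(
            "require -1 < rho_between <= rho_within < 1, got "
            f"{rho_between}, {rho_within}"
        )
    n = atlas.n_nodes
    same = atlas.network_index()[:, None] == atlas.network_index()[None, :]
    cov = np.where(same, rho_within, rho_between)
    np.fill_diagonal(cov, 1.0)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8:
        raise InvalidConfigurationError(
            f"block covariance not PSD (min eigenvalue {evals.min():.3g})"
        )
    factor = evecs * np.sqrt(np.clip(evals, 0, None))
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for s, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        data = factor @ rng.standard_normal((n, n_timepoints))
        out.append(NodeTimeSeries(subject_id=f"sub-{s + 1:03d}", data=data))
    return out


def embed_behavior(edge_vectors: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Behavioral scores as a sparse linear function of edges plus noise.

    y_s = sum_e w_e * x_{s,e} + N(0, noise_sd), reproducible via truth.seed.
    """
    X = np.asarray(edge_vectors, dtype=float)
    if X.ndim != 2:
        raise InvalidConfigurationError("edge_vectors must be subjects × edges")
    idx = truth.signal_edge_indices
    if idx.size and (idx.min() < 0 or idx.max() >= X.shape[1]):
        raise InvalidConfigurationError("signal edge index out of range for edge vectors")
    y = X[:, idx] @ truth.signal_weights
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=X.shape[0])
    return y


def simulate_change_detection_trials(
    params: TrialGenerativeParams, seed: int = 0
) -> TrialCounts:
    """Trial counts under the whole-display guessing model.

    With d = min(true_K / S, 1) the probability the probed item is in memory:
    hit rate d + (1 - d) g, false-alarm rate (1 - d) g, so the expected Cowan
    estimate S (H - F) equals min(true_K, S).
    """
    d = min(params.true_K / params.S, 1.0)
    p_hit = d + (1 - d) * params.g
    p_fa = (1 - d) * params.g
    rng = np.random.default_rng(seed)
    hits = int(rng.binomial(params.n_trials_change, p_hit))
    fas = int(rng.binomial(params.n_trials_nochange, p_fa))
    return TrialCounts(
        S=params.S,
        hits=hits,
        n_change=params.n_trials_change,
        false_alarms=fas,
        n_nochange=params.n_trials_nochange,
    )


def make_ground_truth(
    atlas: AtlasPartition,
    emap: EdgeIndexMap,
    n_signal_edges: int = 30,
    target_network: str = "cerebellum",
    seed: int = 0,
    both_endpoints: bool = True,
    noise_sd: float = 0.0,
) -> GroundTruth:
    """Draw signal edges inside (or touching) the target network."""
    rng = np.random.default_rng(seed)
    nodes = atlas.nodes_of(target_network)
    in_net = np.zeros(atlas.n_nodes, dtype=bool)
    in_net[nodes] = True
    if both_endpoints:
        eligible = np.flatnonzero(in_net[emap.rows] & in_net[emap.cols])
    else:
        eligible = np.flatnonzero(in_net[emap.rows] | in_net[emap.cols])
    if eligible.size < n_signal_edges:
        raise InvalidConfigurationError(
            f"{target_network} supports only {eligible.size} edges, "
            f"requested {n_signal_edges}"
        )
    idx = np.sort(rng.choice(eligible, size=n_signal_edges, replace=False))
    # a common sign keeps per-edge marginal associations from cancelling
    # across positively correlated within-network edges, so each signal edge
    # stays individually detectable (the property the recovery suite tests)
    weights = rng.uniform(0.5, 1.5, size=n_signal_edges)
    truth = GroundTruth(
        signal_edge_indices=idx,
        signal_weights=weights,
        noise_sd=noise_sd,
        target_network=target_network,
        seed=seed,
        both_endpoints=both_endpoints,
    )
    truth.validate(emap, atlas)
    return truth


@dataclass
class SyntheticDataset:
    """A full simulated cohort: atlas, edge features, behavior, and truth."""

    atlas: AtlasPartition
    emap: EdgeIndexMap
    X: np.ndarray  # subjects × edges Fisher-z features
    y: np.ndarray  # behavioral scores
    truth: GroundTruth
    subject_ids: list[str] = field(default_factory=list)
    timeseries: list[NodeTimeSeries] | None = None


def simulate_dataset(
    n_subjects: int = 103,
    n_nodes: int = 268,
    network_sizes=DEFAULT_NETWORK_SIZES,
    network_names=DEFAULT_NETWORK_NAMES,
    n_timepoints: int = 240,
    rho_within: float = 0.3,
    rho_between: float = 0.0,
    n_signal_edges: int = 30,
    target_network: str = "cerebellum",
    snr: float = 1.5,
    seed: int = 0,
    keep_timeseries: bool = False,
) -> SyntheticDataset:
    """Generate a complete cohort with a planted edge-behavior signal.

    ``snr`` is the ratio sd(noiseless linear predictor) / noise_sd, measured
    on the realized cohort, so the planted association has a known strength
    regardless of atlas or edge-weight draws. ``snr=None`` or ``inf`` gives
    noiseless behavior.
    """
    ss = np.random.SeedSequence(seed)
    s_atlas, s_ts, s_truth, s_noise = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    atlas = make_atlas(n_nodes, network_sizes, network_names, seed=s_atlas)
    cohort = simulate_timeseries(
        n_subjects, atlas, n_timepoints, rho_within, rho_between, seed=s_ts
    )
    X, ids, emap = edge_vectors_from_cohort(cohort)
    truth = make_ground_truth(
        atlas, emap, n_signal_edges, target_network, seed=s_truth
    )
    signal = X[:, truth.signal_edge_indices] @ truth.signal_weights
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise InvalidConfigurationError("snr must be positive")
        truth.noise_sd = float(signal.std() / snr)
    truth.seed = s_noise
    y = embed_behavior(X, truth)
    return SyntheticDataset(
        atlas=atlas,
        emap=emap,
        X=X,
        y=y,
        truth=truth,
        subject_ids=ids,
        timeseries=cohort if keep_timeseries else None,
    )
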