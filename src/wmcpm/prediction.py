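"""LOOCV SVR prediction of behavior from connectivity edges.

The procedure, per behavioral component:

1. Leave one subject out; on the remaining subjects fit a linear epsilon-SVR
   on all edges and rank edges by absolute weight (ties broken by lower edge
   index).
2. Keep the top q per-mille of edges (floor, minimum 1), refit the SVR on
   that subset, and predict the held-out subject.
3. Prediction accuracy is the Pearson r between predicted and actual scores
   over all subjects.
4. Significance: permutations reshuffle the scores and re-run the *entire*
   nested procedure, including per-fold feature re-selection; p is the
   proportion of permuted r exceeding the observed r (a bias-corrected
   (k+1)/(n+1) variant is reported alongside).
5. Benjamini-Hochberg FDR across the analysis family (e.g. thresholds ×
   components) flags significant thresholds.

Feature ranking and selection never see the held-out subject, so there is no
leakage from test to train.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._svr import fold_refit_predict, solve_svr_kernel

_MAX_ITER = 2_000_000


@dataclass(frozen=True)
class PredictionConfig:
    """Settings for the LOOCV prediction procedure.

    The SVR is an epsilon-SVR with a linear kernel (required for
    interpretable edge weights) at C=1, epsilon=0.1. Feature standardization
    is off by default: Fisher-z edges already share a common scale; when on,
    means and SDs come from the training fold only.
    """

    per_mille_thresholds: tuple[int, ...] = (1, 3, 5, 7, 9)
    n_permutations: int = 1000
    C: float = 1.0
    epsilon: float = 0.1
    tol: float = 1e-3
    standardize_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.per_mille_thresholds):
            raise ValueError("per-mille thresholds must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class FoldModel:
    """One LOOCV fold: selection and prediction computed without the held-out subject."""

    held_out_subject: int
    selected_edge_indices: np.ndarray
    training_weights: np.ndarray
    prediction: float
    degenerate: bool = False


@dataclass
class ThresholdResult:
    """Prediction outcome at one per-mille feature threshold."""

    per_mille: int
    n_features: int
    r_observed: float
    p_permutation: float | None = None
    p_permutation_unbiased: float | None = None
    q_significant: bool | None = None
    folds: list[FoldModel] = field(default_factory=list)
    consensus_edges: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    null_r: np.ndarray | None = None
    degenerate: bool = False


def feature_count(n_features: int, per_mille: float) -> int:
    """Number of edges kept at a per-mille threshold: floor, minimum 1.

    floor matches the printed endpoints for 35,778 edges (1 permille -> 35,
    9 permille -> 322); rounding would give 36.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if per_mille <= 0:
        raise ValueError("per_mille must be positive")
    if float(per_mille).is_integer():
        k = (n_features * int(per_mille)) // 1000
    else:
        k = math.floor(n_features * per_mille / 1000)
    return max(1, k)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson r with a degenerate flag when either side is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0, True
    r = float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))
    return max(-1.0, min(1.0, r)), False


def _top_k_order(absw: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |weights|, sorted descending, ties by lower index."""
    n = absw.shape[0]
    k = min(k, n)
    if k == n:
        cand = np.arange(n)
    else:
        thr = np.partition(absw, n - k)[n - k]
        cand = np.flatnonzero(absw >= thr)
    order = cand[np.argsort(-absw[cand], kind="stable")]
    return order[:k]


def svr_weights(X: np.ndarray, y: np.ndarray, config: PredictionConfig,
                gram: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Linear SVR primal weights and intercept on (X, y)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if gram is None:
        gram = X @ X.T
    beta, rho, it = solve_svr_kernel(
        np.ascontiguousarray(gram), np.ascontiguousarray(y),
        config.C, config.epsilon, config.tol, _MAX_ITER,
    )
    if it >= _MAX_ITER:
        raise RuntimeError(
            f"SVR solver failed to converge within {_MAX_ITER} iterations "
            f"(n={len(y)}, y range [{y.min():.3g}, {y.max():.3g}])"
        )
    return X.T @ beta, -rho


def rank_features_by_svr(
    X_train: np.ndarray, y_train: np.ndarray, config: PredictionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rank edges by |SVR weight| descending; ties broken by lower edge index.

    Returns (order, weights) with ``weights`` aligned to the original edge
    indexing. A constant training target leaves every weight zero; the
    ordering then falls back to index order, flagged with a warning.
    """
    config = config or PredictionConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if X_train.shape[0] < 3:
        raise ValueError("need at least 3 training subjects")
    w, _ = svr_weights(X_train, y_train, config)
    if not np.any(w):
        warnings.warn("degenerate ranking: all SVR weights are zero", stacklevel=2)
    order = np.argsort(-np.abs(w), kind="stable")
    return order, w


class _LoocvEngine:
    """Shared machinery for observed and permuted LOOCV runs on one dataset.

    The subjects × subjects Gram matrix is computed once per dataset (the
    feature matrix never changes across permutations); each fold's ranking
    fit runs on a sliced Gram, fold weights are recovered in one matrix
    product, and refits on the nested top-k subsets reuse incrementally
    accumulated sub-Grams.
    """

    def __init__(self, X: np.ndarray, config: PredictionConfig):
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.config = config
        self.n, self.p = X.shape
        if not config.standardize_features:
            self.gram = self.X @ self.X.T
        else:
            self.gram = None
        # float32 copy for the bulk ranking products (memory-bandwidth bound)
        self.X32 = self.X.astype(np.float32)

    def ks_for(self, thresholds) -> list[int]:
        return [feature_count(self.p, t) for t in thresholds]

    def run(self, y: np.ndarray, thresholds, collect_folds: bool = False):
        """LOOCV at every threshold at once.

        Returns (preds: dict threshold -> np.ndarray of per-subject
        predictions, folds: dict threshold -> list[FoldModel] | None).
        """
        cfg = self.config
        y = np.ascontiguousarray(y, dtype=np.float64)
        n, p = self.n, self.p
        if n < 4:
            raise ValueError("LOOCV needs at least 4 subjects")
        ks = self.ks_for(thresholds)
        k_max = max(ks)
        order_ks = np.argsort(ks)  # process thresholds in nested (ascending) order

        betas = np.zeros((n, n))
        all_idx = np.arange(n)
        # NB: each fold's ranking fit starts cold — a warm start shared
        # across folds (e.g. from a full-sample fit) would let the held-out
        # subject's score steer the fold's solver path, a leakage channel
        for i in range(n):
            tr = np.delete(all_idx, i)
            if cfg.standardize_features:
                mu = self.X[tr].mean(axis=0)
                sd = self.X[tr].std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                Xs = (self.X - mu) / sd
                G = Xs @ Xs.T
            else:
                G = self.gram
            beta, _, it = solve_svr_kernel(
                np.ascontiguousarray(G[np.ix_(tr, tr)]), y[tr],
                cfg.C, cfg.epsilon, cfg.tol, _MAX_ITER,
            )
            if it >= _MAX_ITER:
                raise RuntimeError(f"ranking SVR did not converge in fold {i}")
            betas[i, tr] = beta

        # fold weight vectors in one product; float32 is ample for ranking
        W = betas.astype(np.float32) @ self.X32
        np.abs(W, out=W)

        preds = {t: np.empty(n) for t in thresholds}
        folds = {t: [] for t in thresholds} if collect_folds else None

        ks_sorted = np.array([ks[t_pos] for t_pos in order_ks], dtype=np.int64)
        for i in range(n):
            tr = np.delete(all_idx, i)
            sel_full = _top_k_order(W[i], k_max)
            if cfg.standardize_features:
                mu = self.X[tr].mean(axis=0)
                sd = self.X[tr].std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                Xsel = (self.X[:, sel_full] - mu[sel_full]) / sd[sel_full]
            else:
                Xsel = self.X[:, sel_full]
            # nested thresholds share incremental sub-Grams and warm starts;
            # the first refit starts from the fold's ranking solution
            fold_preds, fold_iters = fold_refit_predict(
                np.ascontiguousarray(Xsel), y, i, ks_sorted, betas[i, tr],
                cfg.C, cfg.epsilon, cfg.tol, _MAX_ITER,
            )
            if fold_iters.max() >= _MAX_ITER:
                raise RuntimeError(f"prediction SVR did not converge in fold {i}")
            for c, t_pos in enumerate(order_ks):
                t = thresholds[t_pos]
                preds[t][i] = fold_preds[c]
                if collect_folds:
                    sel = sel_full[: ks[t_pos]]
                    folds[t].append(
                        FoldModel(
                            held_out_subject=i,
                            selected_edge_indices=np.sort(sel),
                            training_weights=None,  # filled below
                            prediction=float(fold_preds[c]),
                            degenerate=not np.any(W[i][sel]),
                        )
                    )
        if collect_folds:
            # recover signed ranking-fit weights for the selected edges only
            for t in thresholds:
                for fm in folds[t]:
                    i = fm.held_out_subject
                    sel = fm.selected_edge_indices
                    fm.training_weights = betas[i] @ self.X[:, sel]
        return preds, folds


def _consensus(folds: list[FoldModel]) -> np.ndarray:
    sets = [fm.selected_edge_indices for fm in folds]
    out = sets[0]
    for s in sets[1:]:
        out = np.intersect1d(out, s, assume_unique=True)
        if out.size == 0:
            break
    return out


def loocv_predict(
    X: np.ndarray,
    y: np.ndarray,
    per_mille: int | None = None,
    config: PredictionConfig | None = None,
) -> ThresholdResult | dict[int, ThresholdResult]:
    """LOOCV prediction at one threshold (or all configured thresholds).

    With ``per_mille`` given, returns that threshold's :class:`ThresholdResult`
    (permutation fields unset); otherwise a dict over
    ``config.per_mille_thresholds``, sharing the per-fold ranking fits.
    """
    config = config or PredictionConfig()
    thresholds = (per_mille,) if per_mille is not None else config.per_mille_thresholds
    engine = _LoocvEngine(np.asarray(X, dtype=np.float64), config)
    results = _observed_results(engine, np.asarray(y, dtype=np.float64), thresholds)
    return results[per_mille] if per_mille is not None else results


def _observed_results(engine: _LoocvEngine, y, thresholds) -> dict[int, ThresholdResult]:
    preds, folds = engine.run(y, tuple(thresholds), collect_folds=True)
    out = {}
    for t in thresholds:
        r, degen = _pearson(preds[t], y)
        out[t] = ThresholdResult(
            per_mille=t,
            n_features=feature_count(engine.p, t),
            r_observed=r,
            folds=folds[t],
            consensus_edges=_consensus(folds[t]),
            degenerate=degen,
        )
        if not out[t].consensus_edges.size:
            warnings.warn(f"empty consensus set at {t} permille", stacklevel=3)
    return out


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    config: PredictionConfig | None = None,
    thresholds: tuple[int, ...] | None = None,
    engine: _LoocvEngine | None = None,
) -> dict[int, np.ndarray]:
    """Null distribution of r: shuffle y, re-run the full nested LOOCV.

    One master seed spawns an independent stream per permutation, so the
    null is reproducible and independent of execution order. The same
    shuffles serve every threshold (feature selection is re-done per fold
    within each shuffle).
    """
    config = config or PredictionConfig()
    thresholds = tuple(thresholds or config.per_mille_thresholds)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    engine = engine or _LoocvEngine(X, config)
    null_r = {t: np.empty(config.n_permutations) for t in thresholds}
    streams = np.random.SeedSequence(config.seed).spawn(config.n_permutations)
    for b, ss in enumerate(streams):
        y_perm = np.random.default_rng(ss).permutation(y)
        preds, _ = engine.run(y_perm, thresholds, collect_folds=False)
        for t in thresholds:
            null_r[t][b] = _pearson(preds[t], y_perm)[0]
    return null_r


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    per_mille: int,
    config: PredictionConfig | None = None,
) -> ThresholdResult:
    """Observed LOOCV r plus its permutation p at one threshold.

    ``p_permutation`` is the proportion of permuted r strictly exceeding the
    observed r (it can be exactly 0); ``p_permutation_unbiased`` is the
    (k+1)/(n+1) correction.
    """
    config = config or PredictionConfig()
    engine = _LoocvEngine(np.asarray(X, dtype=np.float64), config)
    y = np.asarray(y, dtype=np.float64)
    res = _observed_results(engine, y, (per_mille,))[per_mille]
    null = permutation_null(X, y, config, (per_mille,), engine=engine)[per_mille]
    _attach_p(res, null)
    return res


def _attach_p(res: ThresholdResult, null_r: np.ndarray) -> None:
    exceed = int(np.sum(null_r > res.r_observed))
    res.null_r = null_r
    res.p_permutation = exceed / len(null_r)
    res.p_permutation_unbiased = (exceed + 1) / (len(null_r) + 1)


def predict_component(
    X: np.ndarray,
    y: np.ndarray,
    config: PredictionConfig | None = None,
    apply_fdr: bool = True,
    alpha: float = 0.05,
) -> dict[int, ThresholdResult]:
    """Full analysis of one component: LOOCV + permutations at every threshold.

    With ``apply_fdr``, BH-corrects across this component's thresholds; when
    several components form one family (e.g. 5 thresholds × 3 components),
    run with ``apply_fdr=False`` and correct jointly via :func:`fdr_correct`.
    """
    config = config or PredictionConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    engine = _LoocvEngine(X, config)
    results = _observed_results(engine, y, config.per_mille_thresholds)
    null = permutation_null(X, y, config, config.per_mille_thresholds, engine=engine)
    for t, res in results.items():
        _attach_p(res, null[t])
    if apply_fdr:
        ts = list(results)
        flags, _ = fdr_correct([results[t].p_permutation for t in ts], alpha=alpha)
        for t, flag in zip(ts, flags):
            results[t].q_significant = bool(flag)
    return results


def fdr_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj
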