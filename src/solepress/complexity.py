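"""Spatial complexity of pressure patterns via non-negative matrix
factorization (NMF).

A recording is flattened to a non-negative matrix X (frames x cells) and
factorized as X ~ W H with W (frames x k) the activation coefficients and
H (k x cells) the spatial components.  Variance explained is uncentred,

    VE(k) = 1 - ||X - W H||_F^2 / ||X||_F^2,

which is the natural definition for a factorization without an intercept.
The spatial complexity of a task is k*, the smallest k whose VE reaches a
threshold (default 90%).  Components recurring across tasks are grouped
by hierarchical clustering of the pairwise Pearson correlations between
their spatial maps, and ranked by the order in which each cluster first
appears as more components per task are pooled.

The factorization uses seeded multiplicative updates (Lee & Seung
Frobenius form), which decrease the reconstruction error monotonically;
each fit keeps the best of ``n_restarts`` deterministic restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .foot_model import PressureRecording

__all__ = [
    "NMFModel",
    "ComplexityResult",
    "ComponentClusterSet",
    "fit_nmf",
    "components_for_threshold",
    "component_correlation_clusters",
    "cluster_emergence_order",
    "subsample_sensitivity",
    "mirror_to_right",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12
DEFAULT_SWEEP_THRESHOLDS = tuple(np.round(np.arange(0.65, 0.951, 0.05), 2))


@dataclass
class NMFModel:
    """One fitted non-negative factorization.

    ``spatial`` rows are unit-sum maps (scale absorbed into activations),
    sorted by total activation energy, descending.
    """

    k: int
    spatial: np.ndarray  # (k, n_cells), >= 0, rows sum to 1
    activations: np.ndarray  # (T, k), >= 0
    variance_explained: float
    seed: int
    n_restarts: int
    n_iter: int = 0
    error_history: np.ndarray | None = None  # squared Frobenius error per iter

    def reconstruction(self) -> np.ndarray:
        return self.activations @ self.spatial


def _mu_nmf(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF; returns (W, H, error history)."""
    T, n = X.shape
    scale = np.sqrt(X.mean() / k) + _EPS
    W = rng.uniform(0.1, 1.0, size=(T, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    errors = []
    prev = None
    for it in range(max_iter):
        WH = W @ H
        H *= (W.T @ X) / (W.T @ WH + _EPS)
        WH = W @ H
        W *= (X @ H.T) / (WH @ H.T + _EPS)
        err = float(np.linalg.norm(X - W @ H) ** 2)
        errors.append(err)
        if prev is not None and prev > 0:
            if abs(prev - err) / prev < tol:
                break
        prev = err
    return W, H, np.array(errors)


def fit_nmf(
    frames: np.ndarray | PressureRecording,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NMFModel:
    """Fit a k-component NMF, keeping the best of seeded restarts.

    Restart r is seeded with ``seed + r``; the model with the lowest final
    reconstruction error wins, ties broken by lower restart index.
    """
    X = frames.flattened() if isinstance(frames, PressureRecording) else np.asarray(frames, dtype=float)
    if X.ndim != 2:
        raise ValueError("frames must be 2-D (T x n_cells)")
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    sq_norm = float(np.linalg.norm(X) ** 2)
    if sq_norm == 0:
        raise ValueError("all-zero input")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k={k} outside 1..min(T, n_cells)={min(X.shape)}")

    best: tuple[float, int, np.ndarray, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        W, H, errors = _mu_nmf(X, k, rng, tol, max_iter)
        final = errors[-1]
        if best is None or final < best[0]:
            best = (final, r, W, H, errors)
    assert best is not None
    final_err, _, W, H, errors = best

    # normalize spatial maps to unit sum, absorb scale into activations
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]
    # sort by total activation energy, descending
    energy = (W**2).sum(axis=0)
    order = np.argsort(-energy, kind="stable")
    W, H = W[:, order], H[order]

    ve = 1.0 - final_err / sq_norm
    return NMFModel(
        k=k, spatial=H, activations=W, variance_explained=float(ve),
        seed=seed, n_restarts=n_restarts, n_iter=len(errors),
        error_history=errors,
    )


@dataclass
class ComplexityResult:
    """k* sweep for one task."""

    k_star: int | None  # None means "> k_max"
    threshold: float
    k_max: int
    ve_by_k: dict[int, float] = field(default_factory=dict)
    sweep: dict[float, int | None] = field(default_factory=dict)
    models: dict[int, NMFModel] = field(default_factory=dict)


def components_for_threshold(
    frames: np.ndarray | PressureRecording,
    threshold: float = 0.90,
    k_max: int = 30,
    seed: int = 0,
    n_restarts: int = 10,
    sweep: bool = False,
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP_THRESHOLDS,
    tol: float = 1e-6,
    max_iter: int = 500,
    keep_models: bool = True,
) -> ComplexityResult:
    """Minimal number of components reaching the VE threshold.

    Fits k = 1, 2, ... until VE >= threshold (or, when ``sweep`` is on,
    until the largest sweep threshold is reached), then reads off k* for
    each requested threshold.  An unreachable threshold yields k* = None.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    X = frames.flattened() if isinstance(frames, PressureRecording) else np.asarray(frames, dtype=float)
    targets = [threshold] + (list(sweep_thresholds) if sweep else [])
    stop_at = max(targets)
    rank_bound = min(X.shape)

    ve_by_k: dict[int, float] = {}
    models: dict[int, NMFModel] = {}
    best_ve = -np.inf
    for k in range(1, min(k_max, rank_bound) + 1):
        model = fit_nmf(X, k, seed=seed, n_restarts=n_restarts,
                        tol=tol, max_iter=max_iter)
        # keep the VE curve monotone: a larger k can always do at least as
        # well, so carry the running best forward
        best_ve = max(best_ve, model.variance_explained)
        ve_by_k[k] = best_ve
        if keep_models:
            models[k] = model
        if best_ve >= stop_at:
            break

    def k_star_for(t: float) -> int | None:
        for k in sorted(ve_by_k):
            if ve_by_k[k] >= t:
                return k
        return None

    k_star = k_star_for(threshold)
    if k_star is None:
        warnings.warn(
            f"VE threshold {threshold} not reached at k_max={k_max}; "
            "k* reported as None (> k_max)", stacklevel=2,
        )
    result = ComplexityResult(
        k_star=k_star, threshold=threshold, k_max=k_max,
        ve_by_k=ve_by_k, models=models,
    )
    if sweep:
        result.sweep = {t: k_star_for(t) for t in sweep_thresholds}
    return result


def mirror_to_right(spatial: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Flip left-foot maps along the ML axis into right-foot orientation."""
    k = spatial.shape[0]
    return spatial.reshape(k, *grid_shape)[:, :, ::-1].reshape(k, -1)


@dataclass
class ComponentClusterSet:
    """Clusters of correlated spatial components pooled across tasks."""

    components: np.ndarray  # (m, n_cells)
    component_ids: list[tuple[str, int]]  # (task, rank-within-task)
    corr: np.ndarray  # (m, m) Pearson correlations
    linkage: np.ndarray
    leaf_order: np.ndarray
    clusters: np.ndarray  # label per component, 1-based
    cluster_centroids: dict[int, np.ndarray]
    cut_distance: float

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centroids)

    def sorted_corr(self) -> np.ndarray:
        return self.corr[np.ix_(self.leaf_order, self.leaf_order)]


def component_correlation_clusters(
    task_components: dict[str, np.ndarray],
    cut_distance: float = 0.5,
) -> ComponentClusterSet:
    """Cluster spatial components pooled across tasks.

    Components are correlated pairwise (Pearson, on vectorized maps),
    hierarchically clustered on distance 1 - r with average linkage, and
    cut at ``cut_distance`` (components correlating above 1 - cut fall in
    one cluster).  Maps must already share the common grid and a common
    (right-foot) orientation; see :func:`mirror_to_right`.
    """
    ids: list[tuple[str, int]] = []
    maps = []
    for task, comps in task_components.items():
        comps = np.asarray(comps, dtype=float)
        for r in range(comps.shape[0]):
            ids.append((task, r))
            maps.append(comps[r])
    if len(maps) < 2:
        raise ValueError("need at least 2 components to cluster")
    M = np.vstack(maps)
    corr = np.corrcoef(M)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaf_order = np.asarray(hierarchy.leaves_list(Z))
    labels = hierarchy.fcluster(Z, t=cut_distance, criterion="distance")
    centroids = {
        int(c): M[labels == c].mean(axis=0) for c in np.unique(labels)
    }
    return ComponentClusterSet(
        components=M, component_ids=ids, corr=corr, linkage=Z,
        leaf_order=leaf_order, clusters=labels,
        cluster_centroids=centroids, cut_distance=cut_distance,
    )


def cluster_emergence_order(
    task_components: dict[str, np.ndarray],
    cut_distance: float = 0.5,
    k_schedule: int | None = None,
) -> list[dict]:
    """Order clusters by the pooled component count at which they first
    appear.

    Components within each task are ranked by activation energy (the
    order :func:`fit_nmf` already returns).  Growing n = 1, 2, ... pools
    each task's top-n components; a cluster of the full analysis is
    "emerged" at the smallest n for which one of its members is pooled,
    i.e. at the minimum within-task rank among its members.  Ties are
    broken by total cluster energy (sum of squared map values as a
    proxy), descending.
    """
    full = component_correlation_clusters(task_components, cut_distance)
    max_rank = max(r for _, r in full.component_ids) + 1
    n_limit = k_schedule if k_schedule is not None else max_rank
    out = []
    for c in np.unique(full.clusters):
        member_idx = np.nonzero(full.clusters == c)[0]
        ranks = [full.component_ids[i][1] + 1 for i in member_idx]
        emerged_at = min(ranks)
        energy = float((full.components[member_idx] ** 2).sum())
        out.append({
            "cluster": int(c),
            "emerged_at_n": int(emerged_at) if emerged_at <= n_limit else None,
            "energy": energy,
            "n_members": len(member_idx),
            "centroid": full.cluster_centroids[int(c)],
        })
    emerged = [d for d in out if d["emerged_at_n"] is not None]
    not_emerged = [d for d in out if d["emerged_at_n"] is None]
    emerged.sort(key=lambda d: (d["emerged_at_n"], -d["energy"]))
    for d in not_emerged:
        d["note"] = "not emerged"
    return emerged + not_emerged


def _greedy_match(corr: np.ndarray) -> list[tuple[int, int]]:
    """Greedy one-to-one matching maximizing correlation (rows x cols)."""
    c = corr.copy()
    pairs = []
    for _ in range(min(c.shape)):
        i, j = np.unravel_index(np.nanargmax(c), c.shape)
        pairs.append((int(i), int(j)))
        c[i, :] = -np.inf
        c[:, j] = -np.inf
    return pairs


def _centroid_cells(spatial_map: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    m = spatial_map.reshape(grid_shape)
    total = m.sum()
    if total <= 0:
        return np.array([np.nan, np.nan])
    rows = np.arange(grid_shape[0]); cols = np.arange(grid_shape[1])
    return np.array([(m.sum(1) @ rows) / total, (m.sum(0) @ cols) / total])


@dataclass
class SensitivityReport:
    k: int
    frame_fraction: float
    matched_correlations: np.ndarray  # (repeats, k)
    centroid_shifts_cells: np.ndarray  # (repeats, k)
    skipped_repeats: int

    @property
    def mean_matched_correlation(self) -> float:
        if self.matched_correlations.size == 0:
            return float("nan")
        return float(np.nanmean(self.matched_correlations))


def subsample_sensitivity(
    frames: np.ndarray | PressureRecording,
    frame_fraction: float = 1.0 / 3.0,
    n_repeats: int = 10,
    seed: int = 0,
    k: int | None = None,
    threshold: float = 0.90,
    grid_shape: tuple[int, int] = (56, 20),
    n_restarts: int = 3,
    **fit_kwargs,
) -> SensitivityReport:
    """Stability of component locations under random frame subsampling.

    Refits k components on each random subset, matches them to the
    full-data components greedily by spatial correlation, and reports per
    component the matched correlation and centroid displacement in cells.
    Repeats whose subset holds fewer frames than k are skipped.
    """
    if not 0.0 < frame_fraction <= 1.0:
        raise ValueError("frame_fraction must be in (0, 1]")
    X = frames.flattened() if isinstance(frames, PressureRecording) else np.asarray(frames, dtype=float)
    if k is None:
        k = components_for_threshold(
            X, threshold=threshold, seed=seed, n_restarts=n_restarts,
            keep_models=False, **fit_kwargs,
        ).k_star
        if k is None:
            raise ValueError("VE threshold unreachable on full data")
    full = fit_nmf(X, k, seed=seed, n_restarts=n_restarts, **fit_kwargs)
    rng = np.random.default_rng(seed)
    T = X.shape[0]
    n_sub = int(round(frame_fraction * T))
    corrs, shifts = [], []
    skipped = 0
    for rep in range(n_repeats):
        idx = rng.choice(T, size=n_sub, replace=False)
        if n_sub < k or X[idx].sum() == 0:
            skipped += 1
            logger.warning("sensitivity repeat %d skipped (subset too small)", rep)
            continue
        sub = fit_nmf(X[idx], k, seed=seed + 1000 + rep,
                      n_restarts=n_restarts, **fit_kwargs)
        cm = np.corrcoef(full.spatial, sub.spatial)[:k, k:]
        pairs = _greedy_match(cm)
        rep_corr = np.full(k, np.nan)
        rep_shift = np.full(k, np.nan)
        for i, j in pairs:
            rep_corr[i] = cm[i, j]
            c_full = _centroid_cells(full.spatial[i], grid_shape)
            c_sub = _centroid_cells(sub.spatial[j], grid_shape)
            rep_shift[i] = float(np.hypot(*(c_full - c_sub)))
        corrs.append(rep_corr)
        shifts.append(rep_shift)
    return SensitivityReport(
        k=k,
        frame_fraction=frame_fraction,
        matched_correlations=np.array(corrs) if corrs else np.empty((0, k)),
        centroid_shifts_cells=np.array(shifts) if shifts else np.empty((0, k)),
        skipped_repeats=skipped,
    )
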