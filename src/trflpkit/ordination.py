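"""Ordination of community profiles: PCA and metric MDS.

Two views of the community data are ordinated:

* PCA on a binary phylotype incidence matrix (samples x phylotypes,
  presence/absence from clone libraries), on the covariance of the
  centered columns — presence/absence columns share a scale, so no
  correlation rescaling is applied;
* two-dimensional metric multidimensional scaling of Euclidean distances
  between relative T-RF peak-area rows, by SMACOF stress majorization
  started from the classical-scaling (principal coordinates)
  configuration.  Raw stress sum_{i<j} (d_ij - |x_i - x_j|)^2 is
  nonincreasing across Guttman-transform iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA


@dataclass
class OrdinationResult:
    """2-D sample coordinates plus per-axis importance (and stress for MDS)."""

    coordinates: pd.DataFrame  # index: sample ids; columns dim1, dim2
    axis_importance: np.ndarray
    stress: float | None = None
    stress_history: np.ndarray | None = None
    method: str = ""


def _as_matrix(matrix) -> pd.DataFrame:
    m = pd.DataFrame(matrix)
    if m.isna().any().any():
        raise ValueError("matrix contains missing values")
    return m


def pca(matrix, n_axes: int = 2) -> OrdinationResult:
    """PCA scores of a (binary) community matrix.

    Columns are centered and the sample covariance eigen-decomposed; the
    first ``n_axes`` component scores are returned together with their
    explained-variance proportions (proportions over all components sum
    to 1).  A constant matrix has no variance to decompose and raises.
    """
    m = _as_matrix(matrix)
    x = m.to_numpy(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 columns")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance")
    model = _SkPCA(svd_solver="full")
    scores = model.fit_transform(x)
    k = min(n_axes, scores.shape[1])
    coords = np.zeros((x.shape[0], n_axes))
    coords[:, :k] = scores[:, :k]
    importance = np.zeros(n_axes)
    importance[:k] = model.explained_variance_ratio_[:k]
    cols = [f"dim{i + 1}" for i in range(n_axes)]
    return OrdinationResult(pd.DataFrame(coords, index=m.index, columns=cols),
                            importance, method="pca")


def classical_scaling(dist: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Principal-coordinates (Torgerson) embedding of a distance matrix."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _raw_stress(dist: np.ndarray, x: np.ndarray) -> float:
    d_hat = squareform(pdist(x))
    iu = np.triu_indices_from(dist, k=1)
    return float(((dist[iu] - d_hat[iu]) ** 2).sum())


def embed_distances(dist: np.ndarray, n_dims: int = 2, max_iter: int = 300,
                    tol: float = 1e-9, seed: int = 0, n_restarts: int = 0,
                    ) -> tuple[np.ndarray, float, np.ndarray]:
    """SMACOF stress majorization of a symmetric distance matrix.

    Starts from the classical-scaling configuration (plus optional random
    restarts seeded by ``seed``); iterates the Guttman transform until the
    raw-stress decrease falls below ``tol`` or ``max_iter`` iterations.
    Returns (configuration, final stress, stress history).  Raw stress is
    guaranteed nonincreasing along the history.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.allclose(dist, dist.T) or (dist < 0).any():
        raise ValueError("distances must be symmetric and nonnegative")
    if np.allclose(dist, 0.0):
        raise ValueError("degenerate distances")

    rng = np.random.default_rng(seed)
    inits = [classical_scaling(dist, n_dims)]
    scale = dist.max()
    for _ in range(n_restarts):
        inits.append(rng.normal(0.0, scale, size=(n, n_dims)))

    best: tuple[np.ndarray, float, np.ndarray] | None = None
    for x in inits:
        x = x - x.mean(axis=0)
        history = [_raw_stress(dist, x)]
        for _ in range(max_iter):
            d_hat = squareform(pdist(x))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_hat > 0, dist / d_hat, 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
            history.append(_raw_stress(dist, x))
            if history[-2] - history[-1] < tol:
                break
        if best is None or history[-1] < best[1]:
            best = (x, history[-1], np.array(history))
    x, stress, history = best
    return x - x.mean(axis=0), stress, history


def mds(matrix, n_dims: int = 2, seed: int = 0, max_iter: int = 300,
        tol: float = 1e-9, n_restarts: int = 0) -> OrdinationResult:
    """Metric MDS of relative T-RF peak-area rows.

    Rows are renormalized to sum to 1 (so the result is invariant to the
    fluorescence scale of each sample), Euclidean distances computed, and
    the configuration found by :func:`embed_distances`.  The final
    configuration is rotated to its principal axes for determinism;
    ``axis_importance`` is each axis's share of the configuration variance.
    """
    m = _as_matrix(matrix)
    x = m.to_numpy(float)
    sums = x.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every sample needs positive total abundance")
    x = x / sums[:, None]
    dist = squareform(pdist(x))
    coords, stress, history = embed_distances(dist, n_dims, max_iter, tol,
                                              seed, n_restarts)
    # rotate to principal axes (does not change pairwise distances)
    _, _, vt = np.linalg.svd(coords - coords.mean(axis=0), full_matrices=False)
    coords = coords @ vt.T
    var = coords.var(axis=0)
    importance = var / var.sum() if var.sum() > 0 else np.zeros(n_dims)
    cols = [f"dim{i + 1}" for i in range(n_dims)]
    return OrdinationResult(pd.DataFrame(coords, index=m.index, columns=cols),
                            importance, stress=stress, stress_history=history,
                            method="mds")


def group_dispersion(result: OrdinationResult, groups) -> pd.DataFrame:
    """Per-group centroid and mean within-group distance to centroid.

    ``groups`` maps every sample id in the ordination to a group label
    (mapping or pandas Series); an unlabeled sample raises.
    """
    labels = pd.Series(groups)
    missing = [s for s in result.coordinates.index if s not in labels.index]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    rows = []
    for group, ids in labels.groupby(labels).groups.items():
        ids = [i for i in ids if i in result.coordinates.index]
        if not ids:
            continue
        pts = result.coordinates.loc[ids].to_numpy(float)
        centroid = pts.mean(axis=0)
        spread = float(np.linalg.norm(pts - centroid, axis=1).mean())
        rows.append({"group": group, "n": len(ids),
                     **{f"centroid_{c}": v for c, v
                        in zip(result.coordinates.columns, centroid)},
                     "spread": spread})
    return pd.DataFrame(rows).set_index("group")


def between_within_ratio(result: OrdinationResult, groups) -> float:
    """Mean between-centroid distance divided by mean within-group spread."""
    disp = group_dispersion(result, groups)
    cents = disp[[c for c in disp.columns if c.startswith("centroid_")]].to_numpy()
    if len(cents) < 2:
        raise ValueError("need at least 2 groups")
    between = pdist(cents).mean()
    within = disp["spread"].mean()
    return float(between / within) if within > 0 else np.inf
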