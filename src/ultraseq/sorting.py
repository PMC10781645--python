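"""Ring sorting of cells and phase extraction.

When the population cycles around a ring-shaped manifold, the loadings of
the cells on the first two principal components wind around the origin;
the quadrant-aware angle of each cell's loading vector is its ring
coordinate, and the angle of the projected population state is the phase
of the oscillation (both in [-pi, pi)). Because a principal component is
only defined up to sign, the basis is canonicalized so that the phase
ascends in time; this makes downstream "ascending-phase" logic
deterministic while leaving every rotation-invariant statistic unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import _downsample_mean, gaussian_smooth
from .session import EventMatrix


@dataclass
class SortOrder:
    order: np.ndarray                 # permutation of cell indices
    theta: Optional[np.ndarray]       # per-cell loading angle (angle variants)
    method: str


@dataclass
class PhaseTrace:
    phi: np.ndarray                   # radians in [-pi, pi), per bin
    bin_size: float
    smoothing_width: Optional[float]
    flagged: np.ndarray               # bins where projection was at the origin
    radius: Optional[np.ndarray] = None  # projection magnitude per bin


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles into [-pi, pi)."""
    return np.mod(np.asarray(angles) + np.pi, 2 * np.pi) - np.pi


def _pca_basis(matrix: np.ndarray):
    """Canonicalized 2-D PCA basis of a cells-x-bins matrix.

    Returns per-cell loadings (N, 2) and per-bin projections (T, 2). The
    sign of the second component is flipped if needed so that the median
    wrapped phase increment of the projected trajectory is positive
    (ascending phase).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3 or matrix.shape[1] < 3:
        raise ValueError("need at least 3 cells and 3 time bins")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(matrix.T)        # (bins, 2)
    loadings = pca.components_.T              # (cells, 2)
    if pca.explained_variance_[1] <= 0:
        raise ValueError("activity matrix has rank < 2")
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    increments = _wrap(np.diff(phi))
    if np.median(increments) < 0:
        loadings = loadings * np.array([1.0, -1.0])
        proj = proj * np.array([1.0, -1.0])
    return loadings, proj


def pca_sort(events: EventMatrix, smoothing_width: Optional[float] = None) -> SortOrder:
    """Sort cells by the angle of their PC1/PC2 loadings.

    In the canonical basis the phase ascends in time, so cells are ordered
    by ascending loading angle: a cell's rank then matches its activation
    order and identified sequences ascend through the sorting (and through
    the ensemble numbering built on it). In the reflected — equally valid —
    basis this is the descending-angle order.
    """
    matrix = events.values.astype(float)
    if smoothing_width is not None:
        matrix = gaussian_smooth(matrix, smoothing_width, events.bin_size)
    loadings, _ = _pca_basis(matrix)
    theta = np.arctan2(loadings[:, 1], loadings[:, 0])
    order = np.argsort(theta, kind="stable")
    return SortOrder(order=order, theta=theta, method="pca")


def sort_by_embedding(embedding: np.ndarray,
                      reference: Optional[SortOrder] = None) -> SortOrder:
    """Angle sort from any external 2-D per-cell embedding.

    The same angle-order rule as :func:`pca_sort` applied to t-SNE, LEM,
    Isomap or UMAP coordinates (which are accepted, not computed). If
    ``reference`` is given the cyclic order is rotated so that the first
    cell coincides with the reference sorting's first cell.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError("embedding must be (n_cells, 2)")
    theta = np.arctan2(embedding[:, 1], embedding[:, 0])
    order = np.argsort(theta, kind="stable")
    if reference is not None:
        first = reference.order[0]
        k = int(np.flatnonzero(order == first)[0])
        order = np.roll(order, -k)
    return SortOrder(order=order, theta=theta, method="embedding")


def oscillation_phase(events: EventMatrix,
                      smoothing_width: Optional[float] = None) -> PhaseTrace:
    """Phase of the oscillation: angle of the population state in PC1/PC2.

    Bins where the projection sits at the origin (no activity) carry the
    previous phase forward and are flagged.
    """
    matrix = events.values.astype(float)
    if smoothing_width is not None:
        matrix = gaussian_smooth(matrix, smoothing_width, events.bin_size)
    _, proj = _pca_basis(matrix)
    norm = np.hypot(proj[:, 0], proj[:, 1])
    eps = 1e-12 * max(norm.max(), 1.0)
    flagged = norm <= eps
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi = _wrap(phi)
    if flagged.any():
        idx = np.where(~flagged, np.arange(phi.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first_valid = int(np.flatnonzero(~flagged)[0]) if (~flagged).any() else 0
        idx[idx < 0] = first_valid
        phi = phi[idx]
    return PhaseTrace(phi=phi, bin_size=events.bin_size,
                      smoothing_width=smoothing_width, flagged=flagged,
                      radius=norm)


def _lagged_correlations(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation of x shifted by each lag in [-max_lag, max_lag]
    against y, computed over the overlapping region."""
    out = np.full(2 * max_lag + 1, np.nan)
    n = x.size
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            a, b = x[lag:], y[:n - lag]
        else:
            a, b = x[:n + lag], y[-lag:]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            continue
        out[k] = np.corrcoef(a, b)[0, 1]
    return out


def correlation_sort(events: EventMatrix, t_osc: float = 8.5,
                     max_lag_points: int = 10,
                     coarse_factor: int = 4) -> SortOrder:
    """Seed-cell correlation sorting.

    Activity is downsampled to 0.52-s bins, smoothed with a Gaussian of
    width 4 * T_osc, and all pairwise lagged correlations up to +-10 coarse
    points (~5 s) are computed. Entry (i, j) of the correlation matrix is
    the peak correlation, negated if the peak falls at a negative lag. The
    row of the globally maximal entry is the seed; the remaining cells are
    ordered by descending correlation with the seed.
    """
    if events.n_cells < 3:
        raise ValueError("need at least 3 cells")
    coarse = _downsample_mean(events.values.astype(float), coarse_factor)
    coarse_bin = events.bin_size * coarse_factor
    smoothed = gaussian_smooth(coarse, 4.0 * t_osc, coarse_bin)
    n = smoothed.shape[0]
    constant = smoothed.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant cells placed last",
                      stacklevel=2)
    C = np.full((n, n), -np.inf)
    lags = np.arange(-max_lag_points, max_lag_points + 1)
    for i in range(n):
        if constant[i]:
            continue
        for j in range(i + 1, n):
            if constant[j]:
                continue
            cc = _lagged_correlations(smoothed[i], smoothed[j], max_lag_points)
            if np.all(np.isnan(cc)):
                continue
            k = int(np.nanargmax(cc))
            peak, lag = cc[k], lags[k]
            C[i, j] = -peak if lag < 0 else peak
            # the (j, i) entry sees the mirrored lag
            C[j, i] = -peak if -lag < 0 else peak
    off = ~np.eye(n, dtype=bool)
    seed = int(np.unravel_index(np.argmax(np.where(off, C, -np.inf)), C.shape)[0])
    key = C[seed].copy()
    key[seed] = np.inf          # seed first
    key[constant] = -np.inf     # constant cells last
    order = np.argsort(-key, kind="stable")
    return SortOrder(order=order, theta=None, method="correlation")


def ring_distances(order: np.ndarray) -> np.ndarray:
    """Pairwise rank distance on the ring, for all unordered cell pairs.

    Distances use periodic boundary conditions: min(|dr|, N - |dr|) where
    dr is the rank difference of the two cells in the sorting.
    """
    order = np.asarray(order)
    n = order.size
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    iu = np.triu_indices(n, k=1)
    dr = np.abs(ranks[iu[0]] - ranks[iu[1]])
    return np.minimum(dr, n - dr)


def sorting_stability(events: EventMatrix, n_shuffles: int = 100,
                      rng: np.random.Generator | None = None) -> dict:
    """Sorting agreement between full-session and half-session sortings.

    Cells are PCA-sorted on the full session and on each half; the three
    vectors of pairwise ring distances are correlated pairwise (Pearson)
    and compared against the 95th percentile of correlations between
    random-position sortings.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_bins = events.n_bins
    if n_bins < 6:
        raise ValueError("session too short to split in halves")
    half = n_bins // 2
    parts = {
        "full": events,
        "first_half": EventMatrix(events.values[:, :half], events.bin_size),
        "second_half": EventMatrix(events.values[:, half:], events.bin_size),
    }
    dists = {k: ring_distances(pca_sort(v).order) for k, v in parts.items()}
    pairs = [("full", "first_half"), ("full", "second_half"),
             ("first_half", "second_half")]
    corr = {f"{a}_vs_{b}": float(np.corrcoef(dists[a], dists[b])[0, 1])
            for a, b in pairs}
    n = events.n_cells
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        d1 = ring_distances(rng.permutation(n))
        d2 = ring_distances(rng.permutation(n))
        null[s] = np.corrcoef(d1, d2)[0, 1]
    cutoff = float(np.percentile(null, 95))
    return {"correlations": corr, "null_cutoff": cutoff,
            "significant": {k: bool(v > cutoff) for k, v in corr.items()}}
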