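"""Topological morphometrics: Euler characteristic curves on annulus-filtered
Gaussian density of a leaf contour point cloud.

The featurization runs, per leaf:

1. a Gaussian density estimate on the normalized contour point cloud — points
   in serrations and sinuses pack neighbors closer and score higher;
2. partition into concentric annuli (default 16) around the geometric center,
   each a smooth Gaussian radial bump kernel;
3. per annulus, a descending sweep over the annulus-weighted density: at each
   threshold the number of connected components of the super-level set
   (points with filtered density above the threshold, joined when within a
   connectivity radius) is recorded — the Euler characteristic curve of the
   0-dimensional complex;
4. the 16 discretized curves are concatenated into one feature vector
   (default 16 x 100 = 1600 non-negative integers) per leaf;
5. vectors are averaged per plant and decomposed by PCA.

Every stage depends only on pairwise distances and center radii, so the
feature vector is exactly invariant under rigid motions of the input contour
and, after normalization, under uniform scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .contours import Contour
from .exceptions import DataError, DegenerateContourError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "TDAConfig",
    "DensityField",
    "AnnulusPartition",
    "FiltrationValues",
    "ECCCurve",
    "PCAResult",
    "gaussian_density",
    "build_annuli",
    "annulus_filter",
    "connectivity_radius",
    "ecc_curve",
    "featurize_leaf",
    "average_plant_features",
    "pca_features",
]

SUPPORT_FLOOR = 1e-8  # relative filtration floor below which points are dropped


@dataclass(frozen=True)
class TDAConfig:
    """Tunable parameters of the featurization.

    All length scales are in normalized-radius units (the contour is scaled to
    maximum radius 1 before featurization).
    """

    n_rings: int = 16
    n_thresholds: int = 100
    bandwidth: float = 0.05
    connectivity_eps_factor: float = 2.5
    n_points: int = 1000
    n_components: int = 20


@dataclass(frozen=True)
class DensityField:
    values: np.ndarray  # one non-negative density per contour point
    bandwidth: float


@dataclass(frozen=True)
class AnnulusPartition:
    radii: np.ndarray  # ring center radii, strictly increasing on (0, 1)
    sigma: float  # radial kernel width

    @property
    def n_rings(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class FiltrationValues:
    values: np.ndarray  # per-point annulus-weighted density for one ring
    support: np.ndarray  # boolean mask of points above the relative floor


@dataclass(frozen=True)
class ECCCurve:
    thresholds: np.ndarray  # descending levels on the normalized [0, 1] scale
    counts: np.ndarray  # connected components of the super-level set


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # vine_id, year, PC1..PCk
    loadings: pd.DataFrame  # one row per component, one column per feature
    percent_variance: np.ndarray  # share of total variance per component, in %


def gaussian_density(contour: Contour | np.ndarray, bandwidth: float) -> DensityField:
    """Average Gaussian kernel density at each contour point.

    density(p) = (1/n) * sum_q exp(-|p - q|^2 / (2 h^2)) over all contour
    points q, self included. The kernel is deliberately unnormalized (no
    1/(2 pi h^2) factor): curves are later computed on a per-leaf
    max-normalized threshold scale, so constant factors cancel.
    """
    if bandwidth <= 0:
        raise ParameterError(f"bandwidth must be positive, got {bandwidth}")
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    d2 = squareform(pdist(pts, "sqeuclidean"))
    values = np.exp(-d2 / (2.0 * bandwidth**2)).mean(axis=1)
    return DensityField(values=values, bandwidth=bandwidth)


def build_annuli(n_rings: int = 16) -> AnnulusPartition:
    """Concentric annulus kernels covering the normalized radius [0, 1].

    Ring centers sit at r_i = (i - 1/2)/n_rings, i = 1..n_rings, with radial
    Gaussian width sigma = half the ring spacing, so adjacent rings overlap
    smoothly rather than cutting hard at ring borders.
    """
    if n_rings < 1:
        raise ParameterError(f"n_rings must be >= 1, got {n_rings}")
    i = np.arange(1, n_rings + 1)
    return AnnulusPartition(radii=(i - 0.5) / n_rings, sigma=0.5 / n_rings)


def annulus_filter(
    contour: Contour | np.ndarray,
    density: DensityField,
    partition: AnnulusPartition,
    ring_index: int,
) -> FiltrationValues:
    """Weight the density by the radial bump of one ring (1-based index).

    w(p) = exp(-(|p| - r_i)^2 / (2 sigma^2)); the filtration value is
    f(p) = w(p) * density(p). Points with f below ``SUPPORT_FLOOR`` times the
    leaf's peak density are outside the ring's support, so a ring far from any
    contour point has an empty support (a valid, all-zero result) rather than
    a degenerate one inflated by its own vanishing maximum.
    """
    if not 1 <= ring_index <= partition.n_rings:
        raise ParameterError(
            f"ring_index must be in [1, {partition.n_rings}], got {ring_index}"
        )
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    radii = np.linalg.norm(pts, axis=1)
    r_i = partition.radii[ring_index - 1]
    w = np.exp(-((radii - r_i) ** 2) / (2.0 * partition.sigma**2))
    f = w * density.values
    dmax = density.values.max() if len(f) else 0.0
    support = f > SUPPORT_FLOOR * dmax if dmax > 0 else np.zeros(len(f), bool)
    if not support.any():
        logger.debug("ring %d has empty support", ring_index)
    return FiltrationValues(values=f, support=support)


def connectivity_radius(points: np.ndarray, factor: float = 2.5) -> float:
    """Connectivity radius = ``factor`` x median nearest-neighbor spacing.

    Guarantees contour-adjacent points connect while points on distant lobes
    do not.
    """
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return float(factor * np.median(dist[:, 1]))


def _component_profile(points: np.ndarray, order: np.ndarray, eps: float) -> np.ndarray:
    """Number of connected components after inserting the first k points of
    ``order`` into the eps-radius graph, for k = 1..n. Incremental union-find:
    each point is united with already-inserted neighbors as it arrives."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    parent = list(range(n))

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    profile = np.empty(n, dtype=np.int64)
    ncomp = 0
    for k, i in enumerate(order):
        ncomp += 1
        for j in adj[i]:
            if rank[j] < k:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
                    ncomp -= 1
        profile[k] = ncomp
    return profile


def ecc_curve(
    contour: Contour | np.ndarray,
    filtration: FiltrationValues,
    n_thresholds: int = 100,
    connectivity_eps: float | None = None,
) -> ECCCurve:
    """Euler characteristic curve of one ring's super-level-set filtration.

    The filtration values are divided by their maximum over the support, and
    ``n_thresholds`` levels equally spaced from 1 down to 0 are swept. At each
    level the count of connected components of the graph on supported points
    with f >= level (edges between points within ``connectivity_eps``) is
    recorded. Implemented incrementally: points are inserted in descending f
    order with union-find, and the per-level count is read off the insertion
    profile, so the whole curve costs one pass.
    """
    if n_thresholds < 2:
        raise ParameterError(f"n_thresholds must be >= 2, got {n_thresholds}")
    f = np.asarray(filtration.values, dtype=float)
    if not np.all(np.isfinite(f)):
        raise DataError("filtration values must be finite")
    thresholds = np.linspace(1.0, 0.0, n_thresholds)
    counts = np.zeros(n_thresholds, dtype=np.int64)
    sup = filtration.support
    if not sup.any() or f[sup].max() <= 0:
        return ECCCurve(thresholds=thresholds, counts=counts)
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    p = pts[sup]
    if connectivity_eps is None:
        connectivity_eps = connectivity_radius(pts)
    elif connectivity_eps <= 0:
        raise ParameterError("connectivity_eps must be positive")
    fs = f[sup] / f[sup].max()
    order = np.argsort(-fs, kind="stable")
    profile = _component_profile(p, order, connectivity_eps)
    fs_sorted = fs[order]
    k_at = np.searchsorted(-fs_sorted, -thresholds, side="right")
    nonzero = k_at > 0
    counts[nonzero] = profile[k_at[nonzero] - 1]
    return ECCCurve(thresholds=thresholds, counts=counts)


def featurize_leaf(contour: Contour, config: TDAConfig = TDAConfig()) -> np.ndarray:
    """Concatenated per-ring ECC counts for one normalized leaf contour.

    Returns an integer vector of length ``n_rings * n_thresholds``
    (default 1600). The contour must be normalized (centroid at origin, max
    radius 1); the connectivity radius is derived from the contour's own
    median nearest-neighbor spacing.
    """
    pts = contour.points
    radii = np.linalg.norm(pts, axis=1)
    if abs(radii.max() - 1.0) > 1e-6 or np.linalg.norm(pts.mean(axis=0)) > 1e-6:
        raise DataError("featurize_leaf requires a normalized contour")
    density = gaussian_density(contour, config.bandwidth)
    partition = build_annuli(config.n_rings)
    eps = connectivity_radius(pts, config.connectivity_eps_factor)
    out = np.empty(config.n_rings * config.n_thresholds, dtype=np.int64)
    for ring in range(1, config.n_rings + 1):
        filt = annulus_filter(contour, density, partition, ring)
        curve = ecc_curve(contour, filt, config.n_thresholds, eps)
        out[(ring - 1) * config.n_thresholds : ring * config.n_thresholds] = curve.counts
    return out


def average_plant_features(features: pd.DataFrame) -> pd.DataFrame:
    """Average leaf feature vectors to one row per (vine_id, year).

    ``features`` holds one row per leaf: ``vine_id``, ``year`` and the feature
    columns (``f_0001``...). All vectors must share the same length.
    """
    if not {"vine_id", "year"}.issubset(features.columns):
        raise DataError("feature table needs vine_id and year columns")
    feat_cols = [c for c in features.columns if c.startswith("f_")]
    if not feat_cols:
        raise DataError("no feature columns (f_*) found")
    if features[feat_cols].isna().any().any():
        raise DataError("feature vectors have missing entries (length mismatch?)")
    return (
        features.groupby(["vine_id", "year"], sort=True)[feat_cols]
        .mean()
        .reset_index()
    )


def feature_frame(records: list[tuple[str, str, int, np.ndarray]]) -> pd.DataFrame:
    """Assemble per-leaf vectors into the feature table.

    ``records`` is a list of (leaf_id, vine_id, year, vector) tuples.
    """
    if not records:
        raise DataError("no feature records")
    length = len(records[0][3])
    for rec in records:
        if len(rec[3]) != length:
            raise DataError("feature vectors have mismatched lengths")
    cols = [f"f_{i + 1:04d}" for i in range(length)]
    df = pd.DataFrame([rec[3] for rec in records], columns=cols)
    df.insert(0, "year", [rec[2] for rec in records])
    df.insert(0, "vine_id", [rec[1] for rec in records])
    df.insert(0, "leaf_id", [rec[0] for rec in records])
    return df


def pca_features(matrix: pd.DataFrame, n_components: int | None = 20) -> PCAResult:
    """Column-mean-centered PCA of the per-plant feature matrix.

    Deterministic full SVD; each component's sign is canonicalized so its
    largest-magnitude loading entry is positive. ``percent_variance`` is each
    component's share of the total variance (summing to 100 over all
    components). ``n_components=None`` keeps every component.
    """
    feat_cols = [c for c in matrix.columns if c.startswith("f_")]
    if not feat_cols:
        feat_cols = [
            c
            for c in matrix.columns
            if c not in ("vine_id", "year", "leaf_id")
            and np.issubdtype(matrix[c].dtype, np.number)
        ]
    X = matrix[feat_cols].to_numpy(float)
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 rows")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateContourError("feature matrix is constant; PCA undefined")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # canonical sign: largest-|loading| entry of each component is positive
    for j in range(k):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    pct = 100.0 * pca.explained_variance_ratio_
    pc_cols = [f"PC{j + 1}" for j in range(k)]
    score_df = pd.DataFrame(scores, columns=pc_cols)
    for col in ("year", "vine_id"):
        if col in matrix.columns:
            score_df.insert(0, col, matrix[col].to_numpy())
    loading_df = pd.DataFrame(loadings, index=pc_cols, columns=feat_cols)
    return PCAResult(scores=score_df, loadings=loading_df, percent_variance=pct)
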