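"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from vineleaf.contours import Contour, normalize_contour, resample_contour


def circle_points(n: int = 1000, radius: float = 1.0) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def ellipse_points(a: float, b: float, n: int = 2000) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(theta), b * np.sin(theta)])


def prepare(points: np.ndarray, n_points: int = 1000) -> Contour:
    """Raw points -> resampled, normalized contour (the standard pre-chain)."""
    return normalize_contour(resample_contour(Contour(points), n_points))


@pytest.fixture
def unit_circle() -> Contour:
    return Contour(circle_points(1000))


@pytest.fixture
def unit_square() -> Contour:
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


def brute_force_ecc(
    points: np.ndarray,
    f: np.ndarray,
    support: np.ndarray,
    thresholds: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Per-level recount of super-level-set components, rebuilding the
    eps-graph from scratch at every threshold (scipy csgraph)."""
    counts = np.zeros(len(thresholds), dtype=int)
    if not support.any() or f[support].max() <= 0:
        return counts
    p = points[support]
    fs = f[support] / f[support].max()
    pairs = cKDTree(p).query_pairs(eps, output_type="ndarray")
    for t, level in enumerate(thresholds):
        mask = fs >= level
        idx = np.flatnonzero(mask)
        n = len(idx)
        if n == 0:
            continue
        remap = -np.ones(len(p), dtype=int)
        remap[idx] = np.arange(n)
        if len(pairs):
            sel = mask[pairs[:, 0]] & mask[pairs[:, 1]]
            rows, cols = remap[pairs[sel, 0]], remap[pairs[sel, 1]]
        else:
            rows = cols = np.empty(0, dtype=int)
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        counts[t] = connected_components(graph, directed=False)[0]
    return counts


def nested_projection_ss(X_blocks: list[np.ndarray], y: np.ndarray) -> list[float]:
    """Sequential SS via explicit orthogonal projections onto the nested
    column spaces (independent of incremental least-squares fitting)."""
    n = len(y)
    prev_proj = np.zeros((n, n))
    out = []
    cum: np.ndarray | None = None
    for block in X_blocks:
        cum = block if cum is None else np.hstack([cum, block])
        proj = cum @ np.linalg.pinv(cum)
        out.append(float(y @ (proj - prev_proj) @ y))
        prev_proj = proj
    return out
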