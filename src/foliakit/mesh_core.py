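"""Mesh graph and geometry primitives.

Adjacency, areas, edge statistics and modal label smoothing on the surface.
Vertex areas use the barycentric (1/3-per-face-corner) attribution so that
region area fractions are exactly additive over vertices.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import FoliakitError
from .types import LabeledSurface

__all__ = [
    "build_adjacency",
    "unique_edges",
    "mean_edge_length",
    "vertex_areas",
    "face_areas",
    "total_area",
    "region_area_fractions",
    "mode_filter_surface",
    "AdjacencyGraph",
]


class AdjacencyGraph:
    """Per-vertex sorted neighbor lists derived from the face set.

    Stored as CSR (``indptr``/``indices``) over the undirected, deduplicated
    edge set.  Symmetric by construction; no self-loops.
    """

    def __init__(self, indptr: np.ndarray, indices: np.ndarray):
        self.indptr = indptr
        self.indices = indices

    @property
    def n_vertices(self) -> int:
        return len(self.indptr) - 1

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v]:self.indptr[v + 1]]

    def degree(self, v: int) -> int:
        return int(self.indptr[v + 1] - self.indptr[v])

    def to_sparse(self) -> sparse.csr_matrix:
        data = np.ones(len(self.indices), dtype=bool)
        n = self.n_vertices
        return sparse.csr_matrix((data, self.indices, self.indptr), shape=(n, n))


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Deduplicated undirected edge set of a triangle list, shape (E, 2)."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def build_adjacency(surface: LabeledSurface) -> AdjacencyGraph:
    """Vertex adjacency graph whose edge set is the union of face edges."""
    n = surface.n_vertices
    e = unique_edges(surface.faces)
    both = np.vstack([e, e[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return AdjacencyGraph(indptr.astype(np.int64), both[:, 1].astype(np.int64))


def face_areas(surface: LabeledSurface) -> np.ndarray:
    v = surface.vertices
    f = surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def total_area(surface: LabeledSurface) -> float:
    return float(face_areas(surface).sum())


def vertex_areas(surface: LabeledSurface) -> np.ndarray:
    """Barycentric vertex areas: each face contributes one third of its area
    to each of its corners.  Sums to the total surface area."""
    fa = face_areas(surface)
    va = np.zeros(surface.n_vertices)
    for c in range(3):
        np.add.at(va, surface.faces[:, c], fa / 3.0)
    return va


def mean_edge_length(surface: LabeledSurface) -> float:
    """Arithmetic mean length (mm) over the unique undirected edge set."""
    e = unique_edges(surface.faces)
    if len(e) == 0:
        raise FoliakitError("surface has no edges")
    d = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    return float(d.mean())


def region_area_fractions(surface: LabeledSurface,
                          exclude: Sequence[int] = ()) -> pd.DataFrame:
    """Per-label surface area and fraction of the cortical total.

    Face area is split 1/3 per corner vertex; the fraction denominator
    excludes background and any ids in ``exclude`` (typically the
    white-matter-tract label that closes the sheet at the peduncle cuts).
    Fractions over included labels sum to 1.

    Returns a DataFrame with columns ``label_id``, ``area_mm2``, ``fraction``
    (fraction is NaN for excluded labels).
    """
    if surface.labels is None:
        raise FoliakitError("surface has no labels")
    va = vertex_areas(surface)
    labels = surface.labels
    ids = np.unique(labels)
    area = {int(i): float(va[labels == i].sum()) for i in ids}
    excluded = set(int(i) for i in exclude) | {0}
    denom = sum(a for i, a in area.items() if i not in excluded)
    if denom <= 0:
        raise FoliakitError("no cortical area left in the fraction denominator")
    rows = []
    for i in sorted(area):
        frac = area[i] / denom if i not in excluded else np.nan
        rows.append((i, area[i], frac))
    return pd.DataFrame(rows, columns=["label_id", "area_mm2", "fraction"])


def _bfs_balls(adj: AdjacencyGraph, radius: int,
               region_labels: Optional[np.ndarray] = None):
    """Per-vertex array of vertices within ``radius`` edges (center included).

    When ``region_labels`` is given, edges crossing a region boundary are
    removed before the ball expansion, so the BFS never leaves the center's
    region.  Implemented as a boolean sparse power ``(A + I)^radius``.
    """
    A = adj.to_sparse()
    if region_labels is not None:
        region_labels = np.asarray(region_labels)
        coo = A.tocoo()
        keep = region_labels[coo.row] == region_labels[coo.col]
        A = sparse.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=A.shape)
    B = (A + sparse.eye(adj.n_vertices, dtype=bool, format="csr")).astype(bool)
    P = B
    for _ in range(radius - 1):
        P = (P @ B).astype(bool)
    P = P.tocsr()
    P.sort_indices()
    return [P.indices[P.indptr[v]:P.indptr[v + 1]]
            for v in range(adj.n_vertices)]


def _ball_mode(labels: np.ndarray, ball: np.ndarray, current: int) -> int:
    """Modal label in a ball; if the current label ties for the mode keep it,
    otherwise the smallest tied id wins."""
    vals, counts = np.unique(labels[ball], return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    if current in winners:
        return current
    return int(winners.min())


def mode_filter_surface(labels: np.ndarray,
                        adjacency: AdjacencyGraph,
                        radius_edges: int = 3,
                        iterations: int = 3,
                        region_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Iterated modal smoothing of per-vertex labels.

    Each vertex is assigned the modal label over its BFS ball of radius
    ``radius_edges`` (center included); all vertices update synchronously and
    the procedure is repeated ``iterations`` times, each pass starting from
    the previous result.  With ``region_mask`` (a per-vertex region id array)
    the ball never crosses region boundaries, so filtering cannot move a
    label across regions.
    """
    if radius_edges < 1:
        raise ValueError("radius_edges must be >= 1")
    labels = np.asarray(labels, dtype=np.int64).copy()
    balls = _bfs_balls(adjacency, radius_edges, region_mask)
    for _ in range(iterations):
        new = labels.copy()
        for v in range(adjacency.n_vertices):
            new[v] = _ball_mode(labels, balls[v], int(labels[v]))
        if np.array_equal(new, labels):
            break
        labels = new
    return labels
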