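"""Binding-site RMSD matrices, Ward agglomeration and medoid extraction.

Ensemble docking needs a handful of receptor conformations that span the
binding-site shapes a trajectory visits.  The route implemented here:
all-atom RMSD over the binding-site selection between every snapshot pair,
Ward hierarchical agglomeration on that matrix, a dendrogram cut at a fixed
height (1.3 Angstrom by default elsewhere), and one medoid snapshot per
cluster as the dockable representative.  A population-density count around
any snapshot quantifies how typical it is of the whole trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structio import AtomSelection, Ensemble

__all__ = [
    "DistanceMatrix",
    "Clustering",
    "pairwise_rmsd_matrix",
    "ward_hac",
    "medoid",
    "population_density",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix (Angstrom) over ensemble frames."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-8):
            raise ValueError("distance matrix must have a zero diagonal")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    """Flat labels, the full merge tree and one medoid frame per cluster.

    ``merge_tree`` rows are ``(i, j, height)`` in scipy linkage convention
    (ids >= n refer to previously formed merges); heights are Angstrom and
    nondecreasing for Ward linkage.
    """

    labels: np.ndarray
    merge_tree: np.ndarray
    medoids: np.ndarray  # frame index per cluster id 0..k-1

    @property
    def n_clusters(self) -> int:
        return int(self.medoids.size)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def _batched_optimal_rmsd_sq(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Squared optimal-superposition RMSD between frames ``rows`` and all
    frames, for pre-centered coordinates ``x`` of shape (n, m, 3).

    Uses the singular-value identity: for centered A, B,
    m * rmsd^2 = |A|^2 + |B|^2 - 2 (s1 + s2 + sign(det H) * s3), H = A^T B.
    """
    n, m, _ = x.shape
    sq = np.einsum("imk,imk->i", x, x)
    h = np.einsum("imk,jml->ijkl", x[rows], x)  # (r, n, 3, 3)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    corr = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
    d2 = (sq[rows][:, None] + sq[None, :] - 2.0 * corr) / m
    return np.maximum(d2, 0.0)


def pairwise_rmsd_matrix(
    e: Ensemble,
    sel: AtomSelection,
    superpose_sel: AtomSelection | None = None,
    superpose: bool = True,
    chunk: int = 64,
) -> DistanceMatrix:
    """All-against-all RMSD over *sel* atoms between ensemble frames.

    Each pair is optimally superposed over *superpose_sel* (default: the
    same binding-site selection) before the deviation is measured; pass
    ``superpose=False`` to take raw coordinate deviations (e.g. after a
    one-off global alignment).
    """
    if e.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sup = superpose_sel if superpose_sel is not None else sel
    n = e.n_frames
    out = np.zeros((n, n))
    same = superpose and np.array_equal(sup.indices, sel.indices)
    if not superpose:
        x = e.coords[:, sel.indices, :]
        for start in range(0, n, chunk):
            rows = np.arange(start, min(start + chunk, n))
            diff = x[rows][:, None] - x[None, :]
            out[rows] = np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
    elif same:
        x = e.coords[:, sel.indices, :]
        x = x - x.mean(axis=1, keepdims=True)
        for start in range(0, n, chunk):
            rows = np.arange(start, min(start + chunk, n))
            out[rows] = np.sqrt(_batched_optimal_rmsd_sq(x, rows))
    else:
        # general case: fit over sup, measure over sel
        xs = e.coords[:, sup.indices, :]
        cen = xs.mean(axis=1, keepdims=True)
        xs = xs - cen
        xm = e.coords[:, sel.indices, :] - cen  # sel centered by sup centroid
        m = sel.indices.size
        for start in range(0, n, chunk):
            rows = np.arange(start, min(start + chunk, n))
            h = np.einsum("jpk,ipl->ijkl", xs, xs[rows])  # rotate j onto i
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(np.einsum("ijkl,ijlm->ijkm", u, vt)))
            vt[..., 2, :] *= d[..., None]
            # R = V' U^T with the reflection-corrected V'
            rot = np.einsum("ijkl,ijlm->ijmk", u, vt)
            rotated = np.einsum("ijkl,jml->ijmk", rot, xm)
            diff = rotated - xm[rows][:, None]
            out[rows] = np.sqrt(diff.reshape(rows.size, n, m * 3).__pow__(2)
                                .sum(axis=-1) / m)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(values=out)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(raw.size, dtype=int)
    for i, lab in enumerate(raw):
        mapping.setdefault(int(lab), len(mapping))
        out[i] = mapping[int(lab)]
    return out


def ward_hac(
    m: DistanceMatrix,
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> Clustering:
    """Ward hierarchical agglomeration on a precomputed distance matrix.

    Uses the Lance-Williams Ward update on squared distances (the ward.D2
    semantics of R's hclust), with heights reported back in Angstrom.
    Clusters are the connected groups of the dendrogram strictly below
    *cut_height*; alternatively request a fixed *n_clusters*.
    """
    if m.n < 2:
        raise ValueError("need at least 2 frames to cluster")
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("give exactly one of cut_height or n_clusters")
    if cut_height is not None and cut_height <= 0:
        raise ValueError("cut_height must be positive")
    z = linkage(squareform(m.values, checks=False), method="ward")
    heights = z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise RuntimeError(
            "non-monotone merge heights: the input matrix is too far from "
            "a metric for Ward agglomeration to be meaningful")
    if cut_height is not None:
        raw = fcluster(z, t=cut_height, criterion="distance")
    else:
        raw = fcluster(z, t=n_clusters, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    k = labels.max() + 1
    clustering = Clustering(labels=labels, merge_tree=z,
                            medoids=np.zeros(k, dtype=int))
    meds = np.array([medoid(clustering, m, c) for c in range(k)], dtype=int)
    clustering.medoids = meds
    return clustering


def medoid(c: Clustering, m: DistanceMatrix, cluster_id: int) -> int:
    """The member frame minimizing mean distance to all other members of its
    cluster; ties resolved to the lowest frame index."""
    members = c.members(cluster_id)
    if members.size == 0:
        raise KeyError(f"unknown or empty cluster {cluster_id}")
    if members.size == 1:
        return int(members[0])
    sub = m.values[np.ix_(members, members)]
    mean_d = sub.sum(axis=1) / (members.size - 1)
    return int(members[np.argmin(mean_d)])  # argmin takes first on ties


def population_density(m: DistanceMatrix, center: int, radius: float) -> int:
    """Number of frames (excluding *center* itself) within *radius* Angstrom
    of the given frame — how populated its neighbourhood is."""
    if not 0 <= center < m.n:
        raise IndexError(f"center {center} out of range")
    if radius <= 0:
        raise ValueError("radius must be positive")
    row = m.values[center]
    count = int(np.sum(row <= radius)) - 1  # diagonal zero counted once
    return count
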