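"""Group-level functional parcellation by spatially constrained Ward
agglomerative clustering of voxel correlation distances.

Subject scans are concatenated per voxel, pairwise Pearson correlations
are computed, and the correlation distance 1 - r (range [0, 2]) feeds an
agglomerative clustering where two clusters may merge only if they contain
at least one pair of spatially neighboring voxels, so every cut of the
dendrogram yields contiguous regions. Ward's minimum-variance criterion is
applied to the supplied distance matrix via the Lance-Williams recurrence
on squared distances (the standard "pre-computed distance" convention).

Voxel adjacency defaults to 6-connectivity (face neighbors); 18- and
26-connectivity are available. Constrained Ward can produce merge-height
inversions; heights are recorded as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic import VoxelDataset

__all__ = [
    "Dendrogram",
    "Atlas",
    "concatenate_group",
    "correlation_matrix",
    "correlation_distance",
    "grid_adjacency",
    "constrained_ward",
    "cut_dendrogram",
    "atlas_overlap_report",
]

#: largest voxel count for which the dense N x N machinery is materialized
DEFAULT_MAX_VOXELS = 4000

_OFFSETS = {
    6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    18: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    26: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)],
}


@dataclass
class Dendrogram:
    """Full agglomerative merge history.

    ``merges`` rows are (cluster_id_a, cluster_id_b, merge_height,
    new_cluster_id) with a < b; leaves are ids 0..n_leaves-1 and merge k
    creates id n_leaves + k. Heights are Ward distances (not guaranteed
    monotone under the spatial constraint).
    """

    merges: list[tuple[int, int, float, int]]
    n_leaves: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["cluster_a", "cluster_b", "height", "new_id"])


@dataclass
class Atlas:
    """Voxel -> region labeling (labels 1..n_regions, no empty region)."""

    voxel_region_labels: np.ndarray
    n_regions: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_region_labels = np.asarray(self.voxel_region_labels, dtype=int)
        self.coords = np.asarray(self.coords, dtype=int)
        present = np.unique(self.voxel_region_labels)
        if not np.array_equal(present, np.arange(1, self.n_regions + 1)):
            raise ValueError("labels must cover 1..n_regions with no empty region")


def concatenate_group(datasets: list[VoxelDataset]) -> VoxelDataset:
    """Concatenate scans row-wise into a single long series per voxel."""
    if not datasets:
        raise ValueError("need at least one dataset")
    ref = datasets[0]
    for d in datasets[1:]:
        if d.coords.shape != ref.coords.shape or not np.array_equal(d.coords, ref.coords):
            diff = np.nonzero(~np.all(d.coords == ref.coords, axis=1))[0] \
                if d.coords.shape == ref.coords.shape else np.array([0])
            raise ValueError(
                f"coordinate mismatch between '{ref.subject_id}' and "
                f"'{d.subject_id}' at voxel {int(diff[0])}")
    series = np.vstack([d.series for d in datasets])
    return VoxelDataset("group", "concat", ref.group_label, ref.coords.copy(), series)


def correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between columns.

    Columns are mean-centered first (a no-op on prewhitened data, whose DC
    bin is zero), so the normalized cross-product matrix is the Pearson
    correlation. Entries are clipped to [-1, 1] and the diagonal is exactly 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("series must be a 2-D matrix with >= 2 rows")
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance column for voxel {int(bad[0])}")
    xn = xc / norms
    c = np.clip(xn.T @ xn, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def correlation_distance(c: np.ndarray) -> np.ndarray:
    """Correlation distance 1 - r; 0 for perfect correlation, 2 for perfect
    anticorrelation."""
    d = 1.0 - np.asarray(c, dtype=float)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def grid_adjacency(coords: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Boolean N x N voxel adjacency under grid connectivity (6/18/26),
    or a fully connected rule with ``connectivity='full'`` (removes the
    spatial constraint)."""
    n = len(coords)
    if connectivity == "full":
        adj = np.ones((n, n), dtype=bool)
        np.fill_diagonal(adj, False)
        return adj
    if connectivity not in _OFFSETS:
        raise ValueError("connectivity must be 6, 18, 26 or 'full'")
    index = {tuple(c): i for i, c in enumerate(np.asarray(coords, dtype=int))}
    adj = np.zeros((n, n), dtype=bool)
    for c, i in index.items():
        for off in _OFFSETS[connectivity]:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                adj[i, j] = adj[j, i] = True
    return adj


def _check_connected(adj: np.ndarray) -> None:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"voxel adjacency graph is disconnected ({n_comp} components); "
            "constrained clustering cannot produce a full dendrogram")


def constrained_ward(d: np.ndarray, coords: np.ndarray,
                     connectivity: int | str = 6,
                     max_voxels: int = DEFAULT_MAX_VOXELS) -> Dendrogram:
    """Spatially constrained agglomerative clustering with Ward linkage.

    At every step, among cluster pairs containing at least one spatially
    adjacent voxel pair, the pair minimizing the Ward criterion is merged
    (Lance-Williams update on squared distances). Ties are broken by the
    lexicographically smallest (cluster_id_a, cluster_id_b).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(coords) != n:
        raise ValueError("distance matrix and coords must agree in size")
    if n > max_voxels:
        raise ValueError(
            f"{n} voxels exceeds the in-memory limit of {max_voxels}; "
            "downsample the grid or raise max_voxels")
    adj = grid_adjacency(coords, connectivity)
    _check_connected(adj)

    s = d.astype(float) ** 2          # squared Ward distances between clusters
    np.fill_diagonal(s, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)
    active = np.ones(n, dtype=bool)
    adj = adj.copy()
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        mask = adj & active[:, None] & active[None, :]
        cand = np.where(mask, s, np.inf)
        mval = cand.min()
        if not np.isfinite(mval):  # pragma: no cover - connectivity guarantees
            raise RuntimeError("no spatially admissible merge remains")
        ii, jj = np.nonzero(cand == mval)
        # tie-break: smallest (min id, max id)
        pairs = sorted(
            {(min(ids[a], ids[b]), max(ids[a], ids[b]), a, b)
             for a, b in zip(ii, jj)})
        id_a, id_b, pa, pb = pairs[0]
        if ids[pa] > ids[pb]:
            pa, pb = pb, pa
        new_id = n + step
        merges.append((id_a, id_b, float(np.sqrt(mval)), new_id))

        ni, nj = sizes[pa], sizes[pb]
        others = active.copy()
        others[[pa, pb]] = False
        nk = sizes[others]
        s_new = ((ni + nk) * s[pa, others] + (nj + nk) * s[pb, others]
                 - nk * mval) / (ni + nj + nk)
        s[pa, others] = s_new
        s[others, pa] = s_new
        s[pa, pa] = np.inf
        active[pb] = False
        sizes[pa] = ni + nj
        adj[pa] |= adj[pb]
        adj[:, pa] |= adj[:, pb]
        adj[pa, pa] = False
        ids[pa] = new_id

    return Dendrogram(merges, n)


def cut_dendrogram(dendro: Dendrogram, k: int, coords: np.ndarray) -> Atlas:
    """Atlas after the first n_leaves - k merges; regions renumbered 1..k in
    order of their smallest member voxel index."""
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"K={k} out of range [1, {n}]")
    parent: dict[int, int] = {}

    def find(c: int) -> int:
        while c in parent:
            c = parent[c]
        return c

    for a, b, _, new_id in dendro.merges[: n - k]:
        parent[a] = new_id
        parent[b] = new_id
    roots = np.array([find(i) for i in range(n)])
    order = {}
    for leaf, root in enumerate(roots):
        order.setdefault(root, leaf)  # first-seen leaf = smallest index
    relabel = {root: r + 1 for r, (root, _) in
               enumerate(sorted(order.items(), key=lambda kv: kv[1]))}
    labels = np.array([relabel[r] for r in roots])
    return Atlas(labels, k, np.asarray(coords, dtype=int))


def atlas_overlap_report(atlas: Atlas, reference: Atlas) -> pd.DataFrame:
    """Per atlas region, the reference labels it overlaps, as percentages
    of the region's voxels, sorted by descending overlap."""
    if atlas.coords.shape != reference.coords.shape or \
            not np.array_equal(atlas.coords, reference.coords):
        raise ValueError("atlas and reference must share the voxel grid")
    rows = []
    for region in range(1, atlas.n_regions + 1):
        in_region = atlas.voxel_region_labels == region
        size = int(in_region.sum())
        ref = reference.voxel_region_labels[in_region]
        vals, counts = np.unique(ref, return_counts=True)
        for v, c in sorted(zip(vals, counts), key=lambda t: (-t[1], t[0])):
            rows.append({"region": region, "reference_label": int(v),
                         "percent_overlap": 100.0 * c / size})
    return pd.DataFrame(rows)
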