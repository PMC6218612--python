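"""Per-subject region graphs and graph-theoretic feature extraction.

Each subject's voxel series are averaged within atlas regions; pairwise
Pearson correlations between region series define a weighted undirected
graph (negative weights zeroed, zero diagonal). A binary graph is obtained
by keeping exactly floor(density * K(K-1)/2) strongest weights — exact-count
rank thresholding, since a scalar weight threshold cannot hit a target
density exactly in the presence of ties. Louvain communities are detected
on the weighted graph.

A documented measure registry produces node measures (one value per node),
pair measures (one value per node pair) and global measures (one value per
graph). Feature assembly adds the mean and standard deviation across
nodes/pairs as two extra features per measure; any feature that is
non-finite for at least one subject is dropped table-wide and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .parcellation import Atlas
from .synthetic import VoxelDataset

__all__ = [
    "SubjectGraph",
    "RegistryConfig",
    "FeatureCatalog",
    "FeatureTable",
    "region_timeseries",
    "weighted_graph",
    "binarize_density",
    "detect_communities",
    "pair_distance",
    "pair_matching_index",
    "pair_gtom",
    "measure_registry",
    "assemble_features",
]


@dataclass
class SubjectGraph:
    """Weighted and (optionally) binarized region-level graph."""

    weights: np.ndarray
    binary: np.ndarray | None = None
    density_target: float | None = None
    communities: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class RegistryConfig:
    """Which measures to compute and their parameters."""

    gtom_m: int = 2
    matching_variant: str = "jaccard"  # or "degree" (BCT-style normalization)
    node_measures: tuple[str, ...] = (
        "degree", "clustering", "local_efficiency", "betweenness",
        "eigenvector_centrality", "participation", "module_zscore",
        "closeness", "coreness", "strength",
    )
    pair_measures: tuple[str, ...] = (
        "distance", "matching_index", "gtom", "edge_betweenness",
        "neighborhood_overlap", "weight",
    )
    global_measures: tuple[str, ...] = (
        "char_path_length", "global_efficiency", "transitivity",
        "assortativity", "modularity", "density", "mean_clustering",
        "largest_component_fraction", "radius", "diameter",
    )


@dataclass
class FeatureCatalog:
    """Ordered feature provenance: (feature_id, measure, scope, nodes)."""

    entries: list[tuple[str, str, str, tuple[int, ...]]]

    @property
    def feature_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass
class FeatureTable:
    """Subjects x features matrix with provenance and drop bookkeeping."""

    frame: pd.DataFrame  # index = subject ids, columns = feature ids
    catalog: FeatureCatalog
    dropped: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.index)


# ---------------------------------------------------------------------------
# graph construction


def region_timeseries(dataset: VoxelDataset, atlas: Atlas) -> np.ndarray:
    """Average voxel series within each region -> T x K matrix."""
    if atlas.coords.shape != dataset.coords.shape or \
            not np.array_equal(atlas.coords, dataset.coords):
        raise ValueError("atlas and dataset voxel grids do not match")
    out = np.empty((dataset.n_timepoints, atlas.n_regions))
    for r in range(1, atlas.n_regions + 1):
        cols = atlas.voxel_region_labels == r
        if not cols.any():
            raise ValueError(f"region {r} is empty")
        out[:, r - 1] = dataset.series[:, cols].mean(axis=1)
    return out


def weighted_graph(region_series: np.ndarray) -> SubjectGraph:
    """Correlation-weighted graph: Pearson r between region series,
    negative weights set to zero, zero diagonal."""
    x = np.asarray(region_series, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    sd = x.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance series for region {int(bad[0]) + 1}")
    w = np.corrcoef(x, rowvar=False)
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return SubjectGraph(weights=w)


def _ranked_pairs(weights: np.ndarray):
    k = weights.shape[0]
    iu, ju = np.triu_indices(k, 1)
    order = sorted(range(len(iu)),
                   key=lambda t: (-weights[iu[t], ju[t]], iu[t], ju[t]))
    return iu, ju, order


def binarize_density(graph: SubjectGraph, density: float = 0.30) -> SubjectGraph:
    """Keep exactly floor(density * K(K-1)/2) strongest weights as edges;
    ties at the cut broken lexicographically by (i, j)."""
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    k = graph.n_nodes
    n_edges = int(np.floor(density * k * (k - 1) / 2))
    iu, ju, order = _ranked_pairs(graph.weights)
    binary = np.zeros((k, k), dtype=int)
    for t in order[:n_edges]:
        binary[iu[t], ju[t]] = binary[ju[t], iu[t]] = 1
    graph.binary = binary
    graph.density_target = density
    return graph


def _nx_weighted(graph: SubjectGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    k = graph.n_nodes
    for i in range(k):
        for j in range(i + 1, k):
            if graph.weights[i, j] > 0:
                g.add_edge(i, j, weight=float(graph.weights[i, j]))
    return g


def _nx_binary(binary: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(binary.shape[0]))
    iu, ju = np.nonzero(np.triu(binary, 1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def detect_communities(graph: SubjectGraph, seed: int = 0) -> np.ndarray:
    """Louvain community partition of the weighted graph (deterministic
    given seed); labels 0..n_communities-1 per node."""
    g = _nx_weighted(graph)
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    labels = np.zeros(graph.n_nodes, dtype=int)
    for c, members in enumerate(parts):
        for node in members:
            labels[node] = c
    graph.communities = labels
    return labels


# ---------------------------------------------------------------------------
# pair measures


def pair_distance(binary: np.ndarray) -> np.ndarray:
    """Unweighted shortest-path length between all node pairs; unreachable
    pairs are +inf; diagonal 0."""
    d = shortest_path(csr_matrix(binary), method="D", unweighted=True,
                      directed=False)
    return d


def pair_matching_index(binary: np.ndarray, variant: str = "jaccard") -> np.ndarray:
    """Similarity of connectivity profiles from common neighbors.

    jaccard: |N(i) & N(j)| / |N(i) | N(j)| with i, j excluded from both
    sets (0 when the union is empty). degree: 2 * common / (k_i + k_j),
    degrees counted after excluding the i-j edge.
    """
    a = np.asarray(binary, dtype=bool)
    k = a.shape[0]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ni = a[i].copy()
            nj = a[j].copy()
            ni[[i, j]] = False
            nj[[i, j]] = False
            common = int(np.sum(ni & nj))
            if variant == "jaccard":
                union = int(np.sum(ni | nj))
                val = common / union if union else 0.0
            elif variant == "degree":
                denom = int(ni.sum()) + int(nj.sum())
                val = 2.0 * common / denom if denom else 0.0
            else:
                raise ValueError(f"unknown matching variant '{variant}'")
            out[i, j] = out[j, i] = val
    return out


def pair_gtom(binary: np.ndarray, m: int = 2) -> np.ndarray:
    """Generalized topological overlap at step m: similarity of the sets of
    nodes reachable in <= m steps (self excluded)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    a = np.asarray(binary, dtype=bool)
    k = a.shape[0]
    d = pair_distance(binary.astype(int))
    reach = (d <= m) & (d > 0)  # N_m(i), excluding i itself
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            common = int(np.sum(reach[i] & reach[j]))
            aij = int(a[i, j])
            denom = min(int(reach[i].sum()), int(reach[j].sum())) + 1 - aij
            val = (common + aij) / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# registry


def _participation(binary: np.ndarray, communities: np.ndarray) -> np.ndarray:
    deg = binary.sum(axis=1).astype(float)
    k = binary.shape[0]
    out = np.zeros(k)
    for i in range(k):
        if deg[i] == 0:
            out[i] = 0.0
            continue
        acc = 0.0
        for c in np.unique(communities):
            kis = binary[i, communities == c].sum()
            acc += (kis / deg[i]) ** 2
        out[i] = 1.0 - acc
    return out


def _module_zscore(binary: np.ndarray, communities: np.ndarray) -> np.ndarray:
    k = binary.shape[0]
    out = np.zeros(k)
    for c in np.unique(communities):
        members = np.nonzero(communities == c)[0]
        within = binary[np.ix_(members, members)].sum(axis=1).astype(float)
        sd = within.std()
        out[members] = (within - within.mean()) / sd if sd > 0 else np.nan
    return out


def _eigenvector_centrality(binary: np.ndarray) -> np.ndarray:
    # principal eigenvector of the adjacency matrix; sign fixed nonnegative
    w, v = np.linalg.eigh(binary.astype(float))
    vec = v[:, np.argmax(w)]
    vec = np.abs(vec)
    s = vec.sum()
    return vec / s if s > 0 else vec


def measure_registry(graph: SubjectGraph,
                     config: RegistryConfig | None = None) -> dict[str, np.ndarray | float]:
    """Compute all enabled measures for one subject graph.

    Returns a map measure_name -> value: length-K vector for node measures,
    K x K symmetric matrix for pair measures, scalar for global measures.
    Non-computable values are non-finite markers, never errors.
    """
    config = config or RegistryConfig()
    if graph.binary is None:
        raise ValueError("graph must be binarized first (binarize_density)")
    if graph.communities is None:
        raise ValueError("graph needs a community partition (detect_communities)")
    binary = graph.binary
    k = graph.n_nodes
    gb = _nx_binary(binary)
    gw = _nx_weighted(graph)
    dist = pair_distance(binary)
    out: dict[str, np.ndarray | float] = {}

    node_fns = {
        "degree": lambda: binary.sum(axis=1).astype(float),
        "clustering": lambda: np.array([nx.clustering(gb, i) for i in range(k)]),
        "local_efficiency": lambda: np.array(
            [nx.global_efficiency(gb.subgraph(list(gb[i])))
             if len(gb[i]) > 1 else 0.0 for i in range(k)]),
        "betweenness": lambda: np.array(
            list(nx.betweenness_centrality(gb, normalized=True).values())),
        "eigenvector_centrality": lambda: _eigenvector_centrality(binary),
        "participation": lambda: _participation(binary, graph.communities),
        "module_zscore": lambda: _module_zscore(binary, graph.communities),
        "closeness": lambda: np.array(
            [nx.closeness_centrality(gb, i) for i in range(k)]),
        "coreness": lambda: np.array(
            [nx.core_number(gb)[i] for i in range(k)], dtype=float),
        "strength": lambda: graph.weights.sum(axis=1),
    }
    for name in config.node_measures:
        out[name] = node_fns[name]()

    def _edge_betweenness() -> np.ndarray:
        eb = nx.edge_betweenness_centrality(gb, normalized=True)
        m = np.zeros((k, k))
        for (i, j), v in eb.items():
            m[i, j] = m[j, i] = v
        return m

    def _neighborhood_overlap() -> np.ndarray:
        a = binary.astype(bool)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                m[i, j] = m[j, i] = np.sum(a[i] & a[j]) / max(k - 2, 1)
        return m

    pair_fns = {
        "distance": lambda: dist,
        "matching_index": lambda: pair_matching_index(binary,
                                                      config.matching_variant),
        "gtom": lambda: pair_gtom(binary, config.gtom_m),
        "edge_betweenness": _edge_betweenness,
        "neighborhood_overlap": _neighborhood_overlap,
        "weight": lambda: graph.weights.copy(),
    }
    for name in config.pair_measures:
        out[name] = pair_fns[name]()

    off = ~np.eye(k, dtype=bool)
    finite_d = dist[off][np.isfinite(dist[off])]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_d = np.where(off & np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    comp_sizes = [len(c) for c in nx.connected_components(gb)]

    def _assortativity() -> float:
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                return float(nx.degree_assortativity_coefficient(gb))
        except Exception:
            return np.nan

    global_fns = {
        "char_path_length": lambda: float(np.mean(dist[off]))
        if np.all(np.isfinite(dist[off])) else np.inf,
        "global_efficiency": lambda: float(inv_d.sum() / (k * (k - 1)))
        if k > 1 else 0.0,
        "transitivity": lambda: float(nx.transitivity(gb)),
        "assortativity": _assortativity,
        "modularity": lambda: float(nx.community.modularity(
            gw, [set(np.nonzero(graph.communities == c)[0])
                 for c in np.unique(graph.communities)], weight="weight"))
        if gw.number_of_edges() > 0 else np.nan,
        "density": lambda: float(binary.sum() / (k * (k - 1))) if k > 1 else 0.0,
        "mean_clustering": lambda: float(nx.average_clustering(gb)),
        "largest_component_fraction": lambda: float(max(comp_sizes) / k),
        "radius": lambda: float(nx.radius(gb)) if nx.is_connected(gb) else np.inf,
        "diameter": lambda: float(nx.diameter(gb)) if nx.is_connected(gb) else np.inf,
    }
    for name in config.global_measures:
        out[name] = global_fns[name]()
    return out


# ---------------------------------------------------------------------------
# feature assembly


def _catalog_for(k: int, config: RegistryConfig) -> FeatureCatalog:
    entries: list[tuple[str, str, str, tuple[int, ...]]] = []
    for name in config.node_measures:
        for i in range(1, k + 1):
            entries.append((f"{name}[n{i}]", name, "node", (i,)))
        entries.append((f"{name}[mean]", name, "mean", ()))
        entries.append((f"{name}[sd]", name, "sd", ()))
    for name in config.pair_measures:
        for i in range(1, k + 1):
            for j in range(i + 1, k + 1):
                entries.append((f"{name}[p{i}-{j}]", name, "pair", (i, j)))
        entries.append((f"{name}[mean]", name, "mean", ()))
        entries.append((f"{name}[sd]", name, "sd", ()))
    for name in config.global_measures:
        entries.append((name, name, "global", ()))
    return FeatureCatalog(entries)


def assemble_features(graphs: dict[str, SubjectGraph],
                      config: RegistryConfig | None = None) -> FeatureTable:
    """Build the subjects x features table from per-subject graphs.

    Per node measure: K per-node features plus mean and sd across nodes;
    per pair measure: K(K-1)/2 per-pair features plus mean and sd across
    pairs (aggregates over finite values only); per global measure one
    feature. Features non-finite for any subject are dropped table-wide.
    """
    config = config or RegistryConfig()
    subjects = list(graphs)
    ks = {g.n_nodes for g in graphs.values()}
    if len(ks) != 1:
        raise ValueError(f"subjects disagree on node count: {sorted(ks)}")
    k = ks.pop()
    catalog = _catalog_for(k, config)
    iu, ju = np.triu_indices(k, 1)
    rows = []
    for sid in subjects:
        reg = measure_registry(graphs[sid], config)
        vals: list[float] = []
        for name in config.node_measures:
            v = np.asarray(reg[name], dtype=float)
            finite = v[np.isfinite(v)]
            vals.extend(v.tolist())
            vals.append(float(finite.mean()) if finite.size else np.nan)
            vals.append(float(finite.std(ddof=1)) if finite.size > 1 else np.nan)
        for name in config.pair_measures:
            m = np.asarray(reg[name], dtype=float)
            v = m[iu, ju]
            finite = v[np.isfinite(v)]
            vals.extend(v.tolist())
            vals.append(float(finite.mean()) if finite.size else np.nan)
            vals.append(float(finite.std(ddof=1)) if finite.size > 1 else np.nan)
        for name in config.global_measures:
            vals.append(float(reg[name]))
        rows.append(vals)
    frame = pd.DataFrame(rows, index=subjects, columns=catalog.feature_ids)
    finite_cols = np.isfinite(frame.to_numpy()).all(axis=0)
    dropped = [c for c, ok in zip(frame.columns, finite_cols) if not ok]
    frame = frame.loc[:, finite_cols]
    kept = set(frame.columns)
    catalog = FeatureCatalog([e for e in catalog.entries if e[0] in kept])
    return FeatureTable(frame, catalog, dropped)
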