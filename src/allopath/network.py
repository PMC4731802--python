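"""Contact-filtered weighted residue network and communication analyses.

Residues are nodes; two residues are connected when any heavy-atom pair
between them lies within a distance cutoff (default 5.5 Å) in at least a
fraction of the frames (default 0.75).  Edge lengths are
w_ij = −log(GC_ij), so strongly correlated contacts are short and
information "flows" preferentially through them.  On this graph the module
computes

* all-pairs shortest communication pathways (Floyd–Warshall, with full
  path reconstruction),
* sub-optimal pathways within a relative length tolerance (default 2 %),
  enumerated by depth-first search with shortest-distance pruning,
* edge betweenness (fractional tie-splitting, or an integer path census),
* Girvan–Newman communities selected by maximum modularity, and
* the community repartition difference (CRD) between two partitions — the
  fraction of node pairs whose co-membership status differs — used to test
  convergence of the community structure against the contact cutoffs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial import cKDTree

from .errors import AlignmentError, AnnotationError, PartitionError
from .trajectory_io import SiteTrajectory, StructureModel, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_CUTOFF = 5.5   # Å, heavy-atom contact
DEFAULT_FRAME_CUTOFF = 0.75     # fraction of frames
DEFAULT_SUBOPT_TOL = 0.02       # relative pathway-length tolerance


@dataclass
class ContactMap:
    """Persistence-filtered residue contacts."""

    fraction: np.ndarray        # (n, n) fraction of frames in contact
    distance_cutoff: float
    frame_cutoff: float

    @property
    def adjacency(self) -> np.ndarray:
        return self.fraction >= self.frame_cutoff

    @property
    def n_residues(self) -> int:
        return self.fraction.shape[0]


@dataclass
class WeightedNetwork:
    """Residue graph; edges carry ``gc``, ``weight`` (=gc) and ``length``.

    ``ground_truth`` holds planted community labels for synthetic graphs.
    """

    graph: nx.Graph
    ground_truth: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nodes(self) -> list:
        return sorted(self.graph.nodes)


@dataclass
class PathResult:
    """One communication pathway through the weighted network."""

    nodes: list
    length: float
    classification: str  # "shortest" | "suboptimal" | "unreachable"

    def recompute_length(self, net: WeightedNetwork) -> float:
        return sum(net.graph[u][v]["length"]
                   for u, v in zip(self.nodes, self.nodes[1:]))


@dataclass
class CommunityPartition:
    """node → community-id map with the partition's modularity."""

    labels: dict
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    @staticmethod
    def from_components(components, q: float = 0.0) -> "CommunityPartition":
        labels = {}
        for comp in sorted((sorted(c) for c in components), key=lambda c: c[0]):
            cid = len(set(labels.values()))
            for node in comp:
                labels[node] = cid
        return CommunityPartition(labels=labels, q=q)


# ---------------------------------------------------------------------------
# Contacts and network construction
# ---------------------------------------------------------------------------

def contact_map(traj: Trajectory | SiteTrajectory,
                model: StructureModel | None = None,
                distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
                frame_cutoff: float = DEFAULT_FRAME_CUTOFF) -> ContactMap:
    """Fraction of frames in which residue pairs are in heavy-atom contact.

    A residue pair is in contact in a frame iff *any* heavy-atom pair
    between the two residues is within ``distance_cutoff``.  With a
    :class:`SiteTrajectory` input the sites themselves act as the (single)
    heavy atoms, which is the natural reading for synthetic site ensembles.
    """
    if isinstance(traj, SiteTrajectory):
        coords = traj.coords
        resindex = np.arange(traj.n_sites)
        n_res = traj.n_sites
    else:
        if model is None:
            raise AnnotationError("all-atom trajectories need a StructureModel")
        heavy = ~model.atom_is_hydrogen
        if not heavy.any():
            raise AnnotationError("model has no heavy atoms")
        for r in range(model.n_residues):
            if len(model.heavy_atom_indices(r)) == 0:
                raise AnnotationError(
                    f"residue {model.res_chains[r]}{model.res_ids[r]} has no "
                    "heavy atoms")
        coords = traj.coords[:, heavy, :]
        resindex = model.atom_resindex[heavy]
        n_res = model.n_residues

    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for frame in coords:
        pairs = cKDTree(frame).query_pairs(distance_cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ri, rj = resindex[pairs[:, 0]], resindex[pairs[:, 1]]
        off = ri != rj
        seen = np.unique(np.stack([np.minimum(ri[off], rj[off]),
                                   np.maximum(ri[off], rj[off])], axis=1), axis=0)
        counts[seen[:, 0], seen[:, 1]] += 1
    counts = counts + counts.T
    frac = counts / coords.shape[0]
    np.fill_diagonal(frac, 0.0)
    return ContactMap(fraction=frac, distance_cutoff=distance_cutoff,
                      frame_cutoff=frame_cutoff)


def build_network(contacts: ContactMap, gc, log_base: float | str = "e",
                  node_meta: dict | None = None) -> WeightedNetwork:
    """Weighted residue network from contacts and generalized correlations.

    Edges exist for contact pairs with GC > 0 and carry length
    w_ij = −log(GC_ij) under the chosen log base (natural by default; the
    base uniformly rescales all lengths and so never changes path orderings
    or the relative sub-optimality rule).
    """
    gc_arr = gc if isinstance(gc, np.ndarray) else gc.gc
    n = contacts.n_residues
    if gc_arr.shape[0] != n:
        raise AlignmentError(
            f"contact map has {n} residues but GC matrix has {gc_arr.shape[0]}")
    scale = 1.0 if log_base in ("e", np.e) else float(np.log(log_base))
    G = nx.Graph()
    G.add_nodes_from(range(n))
    if node_meta:
        nx.set_node_attributes(G, node_meta)
    adj = contacts.adjacency
    n_dropped = n_zero_length = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            g = float(gc_arr[i, j])
            if g <= 0.0:
                n_dropped += 1
                continue
            if g >= 1.0:
                g = 1.0
                n_zero_length += 1
            G.add_edge(i, j, gc=g, weight=g, length=float(-np.log(g)) / scale)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} contact edge(s) with GC = 0 "
                      "(infinite length)", stacklevel=2)
    if n_zero_length:
        logger.warning("%d edge(s) have GC = 1, i.e. zero length; degenerate "
                       "shortest paths possible", n_zero_length)
    return WeightedNetwork(graph=G)


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------

def _length_matrix(net: WeightedNetwork) -> tuple[np.ndarray, list]:
    nodes = net.nodes()
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    M = np.full((n, n), np.inf)
    np.fill_diagonal(M, 0.0)
    for u, v, data in net.graph.edges(data=True):
        M[index[u], index[v]] = M[index[v], index[u]] = data["length"]
    return M, nodes


def all_pairs_shortest(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray, list]:
    """Floyd–Warshall all-pairs distances and predecessors.

    Returns ``(dist, predecessors, nodes)`` with matrix rows/columns in
    ``nodes`` order (sorted node ids).
    """
    M, nodes = _length_matrix(net)
    dist, pred = floyd_warshall(M, directed=False, return_predecessors=True)
    return dist, pred, nodes


def _reconstruct(pred: np.ndarray, nodes: list, s: int, t: int) -> list:
    path = [t]
    while path[-1] != s:
        p = pred[s, path[-1]]
        if p < 0:
            return []
        path.append(int(p))
    return [nodes[i] for i in reversed(path)]


def shortest_path(net: WeightedNetwork, source, target) -> PathResult:
    """Globally shortest communication pathway between two residues.

    Unreachable pairs yield a ``classification="unreachable"`` result with
    infinite length rather than an exception.
    """
    dist, pred, nodes = all_pairs_shortest(net)
    index = {u: i for i, u in enumerate(nodes)}
    s, t = index[source], index[target]
    if not np.isfinite(dist[s, t]):
        return PathResult(nodes=[], length=np.inf, classification="unreachable")
    return PathResult(nodes=_reconstruct(pred, nodes, s, t),
                      length=float(dist[s, t]), classification="shortest")


def suboptimal_paths(net: WeightedNetwork, source, target,
                     tolerance: float = DEFAULT_SUBOPT_TOL,
                     max_paths: int = 10_000) -> list[PathResult]:
    """All simple pathways within ``(1 + tolerance)`` of the shortest length.

    Enumerated by depth-first search pruned with exact shortest-distance-to-
    target lower bounds, so only branches that can still finish within the
    bound are explored.  Sorted by (length, node sequence); truncated at
    ``max_paths`` with a warning, never silently.
    """
    sp = shortest_path(net, source, target)
    if sp.classification == "unreachable":
        return [sp]
    bound = sp.length * (1.0 + tolerance) + 1e-12
    d_to_t = nx.single_source_dijkstra_path_length(net.graph, target,
                                                   weight="length")
    G = net.graph
    results: list[PathResult] = []
    truncated = False

    stack = [(source, [source], 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == target:
            results.append(PathResult(nodes=path, length=length,
                                      classification="suboptimal"))
            if len(results) > max_paths:
                truncated = True
                break
            continue
        # deterministic order: explore smallest neighbour last (stack → first)
        for nbr in sorted(G[node], reverse=True):
            if nbr in path:
                continue
            new_len = length + G[node][nbr]["length"]
            if nbr not in d_to_t or new_len + d_to_t[nbr] > bound:
                continue
            stack.append((nbr, path + [nbr], new_len))

    results.sort(key=lambda p: (p.length, p.nodes))
    if results and results[0].length <= sp.length + 1e-12:
        results[0].classification = "shortest"
    if truncated:
        results = results[:max_paths]
        warnings.warn(f"suboptimal path enumeration truncated at {max_paths} "
                      "paths", stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# Betweenness, communities, modularity
# ---------------------------------------------------------------------------

def edge_betweenness(net: WeightedNetwork, mode: str = "fractional") -> dict:
    """Number of all-pairs shortest pathways crossing each edge.

    ``mode="fractional"`` splits ties among equal-length shortest paths
    (the standard convention); ``mode="census"`` counts one reconstructed
    Floyd–Warshall path per unordered pair, giving integer counts.
    """
    if mode == "fractional":
        bt = nx.edge_betweenness_centrality(net.graph, normalized=False,
                                            weight="length")
        return {tuple(sorted(e)): v for e, v in bt.items()}
    if mode != "census":
        raise ValueError(f"unknown mode {mode!r}")
    dist, pred, nodes = all_pairs_shortest(net)
    counts = {tuple(sorted(e)): 0 for e in net.graph.edges}
    n = len(nodes)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            path = _reconstruct(pred, nodes, s, t)
            for u, v in zip(path, path[1:]):
                counts[tuple(sorted((u, v)))] += 1
    return counts


def modularity(net: WeightedNetwork, partition: CommunityPartition,
               weight: str | None = "weight") -> float:
    """Newman–Girvan modularity Q = Σ_c (e_cc − a_c²) with weighted strengths.

    ``e_cc`` is the fraction of total edge weight inside community c and
    ``a_c`` the fraction of weighted degree attached to c.  ``weight=None``
    treats the graph as unweighted.
    """
    G = net.graph
    if set(partition.labels) != set(G.nodes):
        raise PartitionError("partition does not cover the node set exactly")
    if len(set(partition.labels.values())) == 1:
        return 0.0  # e_cc = a_c = 1 identically
    m = sum(d.get(weight, 1.0) if weight else 1.0
            for _, _, d in G.edges(data=True))
    if m == 0:
        return 0.0
    e = {}
    a = {}
    for u, v, d in G.edges(data=True):
        w = (d.get(weight, 1.0) if weight else 1.0) / m
        cu, cv = partition.labels[u], partition.labels[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        a[cu] = a.get(cu, 0.0) + w / 2.0
        a[cv] = a.get(cv, 0.0) + w / 2.0
    return float(sum(e.get(c, 0.0) - a.get(c, 0.0) ** 2 for c in set(partition.labels.values())))


def girvan_newman(net: WeightedNetwork, weight: str | None = "weight"
                  ) -> CommunityPartition:
    """Girvan–Newman community detection, best partition by modularity.

    Iteratively removes the highest-betweenness edge (weighted shortest
    paths over edge lengths; betweenness ties broken by lexicographically
    smallest edge) and records a candidate partition whenever a component
    splits.  Returns the partition with maximum modularity, evaluated on
    the *original* graph; if no split beats the single-community Q = 0, the
    single community is returned.
    """
    G = net.graph
    if G.number_of_nodes() == 0:
        raise PartitionError("empty network")
    best = CommunityPartition.from_components(nx.connected_components(G))
    best.q = modularity(net, best, weight=weight)
    H = G.copy()
    n_comp = nx.number_connected_components(H)
    while H.number_of_edges():
        bt = nx.edge_betweenness_centrality(H, normalized=False, weight="length")
        # ties: highest betweenness, then lexicographically smallest edge
        top = max(bt.values())
        candidates = sorted(tuple(sorted(e)) for e, v in bt.items()
                            if v >= top - 1e-12)
        H.remove_edge(*candidates[0])
        c = nx.number_connected_components(H)
        if c > n_comp:
            n_comp = c
            cand = CommunityPartition.from_components(nx.connected_components(H))
            cand.q = modularity(net, cand, weight=weight)
            if cand.q > best.q + 1e-12:
                best = cand
    return best


def crd(p1: CommunityPartition, p2: CommunityPartition,
        denominator: str = "pairs") -> float:
    """Community repartition difference between two partitions, in [0, 1].

    The co-membership indicator z(n_i, n_j, c) is 1 when both nodes share a
    community under partition c.  CRD is the number of unordered node pairs
    whose indicator differs between the two partitions, divided by the
    total number of unordered pairs N(N−1)/2 (``denominator="pairs"``) or
    by N² including ordered pairs and self-pairs (``denominator="ordered"``,
    for which self-pairs never differ).
    """
    if set(p1.labels) != set(p2.labels):
        raise AlignmentError("partitions are over different node sets")
    nodes = sorted(p1.labels)
    l1 = np.array([p1.labels[u] for u in nodes])
    l2 = np.array([p2.labels[u] for u in nodes])
    z1 = l1[:, None] == l1[None, :]
    z2 = l2[:, None] == l2[None, :]
    differ = z1 != z2
    n = len(nodes)
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    n_diff = int(differ[iu].sum())
    if denominator == "pairs":
        return n_diff / (n * (n - 1) / 2)
    if denominator == "ordered":
        return 2 * n_diff / (n * n)
    raise ValueError(f"unknown denominator {denominator!r}")


def cutoff_scan(traj, gc, distance_grid, frame_grid,
                model: StructureModel | None = None,
                crd_tolerance: float = 0.02) -> pd.DataFrame:
    """Community convergence against the contact cutoffs.

    Builds the network and its optimal Girvan–Newman partition at every
    (distance, frame) grid point, then reports the CRD between partitions
    at neighbouring grid points.  Grid points yielding an empty network are
    recorded as missing (CRD = NaN against their neighbours).  Rows with
    CRD below ``crd_tolerance`` are flagged as converged; a contiguous run
    of converged rows is the cutoff plateau.
    """
    distance_grid = list(distance_grid)
    frame_grid = list(frame_grid)
    if not distance_grid or not frame_grid:
        raise ValueError("grids must be non-empty")
    partitions: dict[tuple, CommunityPartition | None] = {}
    for dcut in distance_grid:
        for fcut in frame_grid:
            cm = contact_map(traj, model=model, distance_cutoff=dcut,
                             frame_cutoff=fcut)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = build_network(cm, gc)
            if net.graph.number_of_edges() == 0:
                logger.warning("empty network at distance=%.2f frame=%.2f; "
                               "recorded as missing", dcut, fcut)
                partitions[(dcut, fcut)] = None
            else:
                partitions[(dcut, fcut)] = girvan_newman(net)

    rows = []
    def _crd_or_nan(a, b):
        pa, pb = partitions[a], partitions[b]
        if pa is None or pb is None:
            return np.nan
        return crd(pa, pb)

    for fcut in frame_grid:
        for d1, d2 in zip(distance_grid, distance_grid[1:]):
            v = _crd_or_nan((d1, fcut), (d2, fcut))
            rows.append(("distance", d1, d2, fcut, fcut, v))
    for dcut in distance_grid:
        for f1, f2 in zip(frame_grid, frame_grid[1:]):
            v = _crd_or_nan((dcut, f1), (dcut, f2))
            rows.append(("frame", dcut, dcut, f1, f2, v))
    df = pd.DataFrame(rows, columns=["axis", "distance_1", "distance_2",
                                     "frame_1", "frame_2", "crd"])
    df["converged"] = df["crd"] < crd_tolerance
    return df


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def write_edges_tsv(net: WeightedNetwork, path: str,
                    header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("node_i\tnode_j\tgc\tlength\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            d = net.graph[u][v]
            fh.write(f"{u}\t{v}\t{d['gc']:.10g}\t{d['length']:.10g}\n")


def read_edges_tsv(path: str) -> WeightedNetwork:
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("node_i"):
                continue
            u, v, g, w = line.split()
            G.add_edge(int(u), int(v), gc=float(g), weight=float(g),
                       length=float(w))
    return WeightedNetwork(graph=G)


def write_communities_tsv(partition: CommunityPartition, path: str,
                          header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(f"# modularity={partition.q:.10g} "
                 f"n_communities={partition.n_communities}\n")
        fh.write("node\tcommunity\n")
        for node in sorted(partition.labels):
            fh.write(f"{node}\t{partition.labels[node]}\n")
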