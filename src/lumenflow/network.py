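"""Planar tubular-network graphs: builders, IO and cycle-basis machinery.

A tubular network is a planar graph whose edges are fluid-filled cylinders
(tubules) of common radius R and whose nodes are tubule junctions.  Peripheral
nodes may be flagged as *exit* nodes (connected to a large reservoir at a
common reference pressure) and, for the perinuclear-reservoir scenarios, as
*sheet* nodes.  Coordinates and lengths are in micrometres throughout.
"""

from __future__ import annotations

import csv
import json
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi

#: default tubule radius, µm (30 nm)
DEFAULT_RADIUS = 0.03

ROLES = ("normal", "exit", "sheet")


class NetworkError(ValueError):
    """A network violates a structural invariant."""


class ParseError(NetworkError):
    """A network file is malformed; the message carries record context."""


class GenerationError(RuntimeError):
    """The synthetic-network generator failed to meet its constraints."""


@dataclass
class TubularNetwork:
    """A planar tubular network.

    Attributes
    ----------
    node_ids : (N,) int array of node identifiers (arbitrary, unique).
    pos : (N, 2) float array of node coordinates in µm.
    roles : list of ``{"normal", "exit", "sheet"}`` per node.
    edges : (E, 2) int array of node-id pairs.
    lengths : (E,) float array, µm.
    radii : (E,) float array, µm.
    metadata : free-form provenance record.
    """

    node_ids: np.ndarray
    pos: np.ndarray
    roles: list
    edges: np.ndarray
    lengths: np.ndarray
    radii: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.pos = np.asarray(self.pos, dtype=float)
        self.roles = list(self.roles)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self._index = {int(n): i for i, n in enumerate(self.node_ids)}
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, node_id: int) -> int:
        return self._index[int(node_id)]

    @property
    def edge_indices(self) -> np.ndarray:
        """(E, 2) array of positional node indices for each edge."""
        return np.array(
            [[self._index[int(i)], self._index[int(j)]] for i, j in self.edges],
            dtype=int,
        ).reshape(-1, 2)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edge_indices:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def exit_nodes(self) -> np.ndarray:
        return self.node_ids[[r == "exit" for r in self.roles]]

    @property
    def sheet_nodes(self) -> np.ndarray:
        return self.node_ids[[r == "sheet" for r in self.roles]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, (x, y), role in zip(self.node_ids, self.pos, self.roles):
            g.add_node(int(nid), x=float(x), y=float(y), role=role)
        for (i, j), l, r in zip(self.edges, self.lengths, self.radii):
            g.add_edge(int(i), int(j), length=float(l), radius=float(r))
        return g

    def adjacency(self) -> dict:
        """node index -> sorted list of (edge index, neighbour index)."""
        adj: dict = {i: [] for i in range(self.n_nodes)}
        for e, (i, j) in enumerate(self.edge_indices):
            adj[i].append((e, j))
            adj[j].append((e, i))
        for i in adj:
            adj[i].sort(key=lambda t: t[1])
        return adj

    def with_roles(self, roles: list) -> "TubularNetwork":
        return TubularNetwork(
            self.node_ids.copy(), self.pos.copy(), list(roles),
            self.edges.copy(), self.lengths.copy(), self.radii.copy(),
            dict(self.metadata),
        )

    # -- validation ---------------------------------------------------------
    def validate(self):
        if len(self.pos) != self.n_nodes or len(self.roles) != self.n_nodes:
            raise NetworkError("node arrays have inconsistent lengths")
        if len(set(self._index)) != self.n_nodes:
            raise NetworkError("duplicate node ids")
        for r in self.roles:
            if r not in ROLES:
                raise NetworkError(f"unknown node role {r!r}")
        if self.n_edges != len(self.lengths) or self.n_edges != len(self.radii):
            raise NetworkError("edge arrays have inconsistent lengths")
        if np.any(self.lengths <= 0):
            raise NetworkError("all edge lengths must be positive")
        if np.any(self.radii <= 0):
            raise NetworkError("all edge radii must be positive")
        seen = set()
        for k, (i, j) in enumerate(self.edges):
            if i == j:
                raise NetworkError(f"edge {k} is a self-loop on node {i}")
            if int(i) not in self._index or int(j) not in self._index:
                raise NetworkError(f"edge {k} references unknown node")
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if key in seen:
                raise NetworkError(f"duplicate edge {key}")
            seen.add(key)
        if not self.metadata.get("length_override", False):
            ei = self.edge_indices
            d = np.linalg.norm(self.pos[ei[:, 0]] - self.pos[ei[:, 1]], axis=1)
            bad = np.abs(d - self.lengths) > 1e-9
            if np.any(bad):
                k = int(np.argmax(bad))
                raise NetworkError(
                    f"edge {tuple(self.edges[k])}: stored length {self.lengths[k]} "
                    f"differs from Euclidean distance {d[k]}"
                )
        if self.n_nodes > 1 and not self._connected():
            raise NetworkError("network graph is not connected")

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for _, v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_nodes


@dataclass
class CycleBasis:
    """BFS spanning tree plus one fundamental cycle per non-tree edge.

    ``cycles`` holds node-id sequences; each sequence starts and ends at the
    endpoints of its generating non-tree edge, so appending that edge closes
    the loop.  ``cycle_edges`` gives, per cycle, the list of
    ``(edge index, orientation)`` pairs traversed (orientation +1 when the
    cycle follows the stored edge direction i→j).
    """

    tree_edges: list
    cycles: list
    cycle_edges: list

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def bfs_spanning_tree(adjacency: dict, start: int):
    """Deterministic BFS spanning tree (neighbours visited in ascending order).

    Returns (parent, parent_edge, depth, order): arrays indexed by node, with
    parent[start] == -1.
    """
    n = len(adjacency)
    parent = np.full(n, -1, dtype=int)
    parent_edge = np.full(n, -1, dtype=int)
    depth = np.full(n, -1, dtype=int)
    depth[start] = 0
    order = [start]
    q = deque([start])
    while q:
        u = q.popleft()
        for e, v in adjacency[u]:
            if depth[v] < 0:
                depth[v] = depth[u] + 1
                parent[v] = u
                parent_edge[v] = e
                order.append(v)
                q.append(v)
    if len(order) != n:
        raise NetworkError("graph is disconnected; cannot build spanning tree")
    return parent, parent_edge, depth, order


def tree_path(parent: np.ndarray, depth: np.ndarray, a: int, b: int) -> list:
    """Node-index path a→b inside a spanning tree (via the lowest ancestor)."""
    pa, pb = [a], [b]
    ua, ub = a, b
    while depth[ua] > depth[ub]:
        ua = parent[ua]
        pa.append(ua)
    while depth[ub] > depth[ua]:
        ub = parent[ub]
        pb.append(ub)
    while ua != ub:
        ua = parent[ua]
        pa.append(ua)
        ub = parent[ub]
        pb.append(ub)
    return pa + pb[-2::-1]


def _generic_cycle_basis(n_nodes: int, edge_list: np.ndarray, start: int = 0):
    """Cycle basis on an index-based graph; see :func:`compute_cycle_basis`.

    Returns (tree edge indices, cycles as node-index lists, per-cycle
    (edge, orientation) lists, parent, parent_edge, depth).
    """
    adj: dict = {i: [] for i in range(n_nodes)}
    for e, (i, j) in enumerate(edge_list):
        adj[int(i)].append((e, int(j)))
        adj[int(j)].append((e, int(i)))
    for i in adj:
        adj[i].sort(key=lambda t: t[1])
    parent, parent_edge, depth, _ = bfs_spanning_tree(adj, start)
    tree = set(int(e) for e in parent_edge if e >= 0)
    edge_lookup = {}
    for e, (i, j) in enumerate(edge_list):
        edge_lookup[(int(i), int(j))] = (e, 1)
        edge_lookup[(int(j), int(i))] = (e, -1)
    cycles = []
    cycle_edges = []
    for e, (i, j) in enumerate(edge_list):
        if e in tree:
            continue
        path = tree_path(parent, depth, int(j), int(i))  # j .. i inside tree
        # cycle node sequence i, j, ..., i: the generating edge appears once
        seq = [(e, 1)]
        for a, b in zip(path[:-1], path[1:]):
            seq.append(edge_lookup[(a, b)])
        cycles.append([int(i), *path])
        cycle_edges.append(seq)
    return sorted(tree), cycles, cycle_edges, parent, parent_edge, depth


def compute_cycle_basis(net: TubularNetwork) -> CycleBasis:
    """Spanning tree (BFS from the lowest node id, ascending neighbour order)
    and the fundamental cycle of each non-tree edge.

    The basis has exactly E − N + 1 cycles (the graph rank).
    """
    start = int(np.argmin(net.node_ids))
    tree, cycles_idx, cycle_edges, *_ = _generic_cycle_basis(
        net.n_nodes, net.edge_indices, start=start)
    cycles = [[int(net.node_ids[v]) for v in c] for c in cycles_idx]
    tree_pairs = [tuple(int(x) for x in net.edges[e]) for e in tree]
    return CycleBasis(tree_pairs, cycles, cycle_edges)


# -- builders ----------------------------------------------------------------

def build_honeycomb(rows: int, cols: int, edge_length: float = 1.0,
                    radius: float = DEFAULT_RADIUS) -> TubularNetwork:
    """Regular honeycomb (hexagonal) lattice of ``rows`` × ``cols`` hexagons.

    Every interior node has degree 3 and every edge has length
    ``edge_length`` (µm).  Boundary nodes (degree < 3) are given the ``exit``
    role so that contraction-driven flows can vent to a reservoir.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    # integer corner lattice: x = X*(sqrt(3)/2)*s, y = Y*(1/2)*s
    corners = {}
    edges = set()

    def corner(X, Y):
        key = (X, Y)
        if key not in corners:
            corners[key] = None
        return key

    for r in range(rows):
        for q in range(cols):
            cx = 2 * q + (r % 2)
            cy = 3 * r
            ring = [
                (cx, cy + 2), (cx + 1, cy + 1), (cx + 1, cy - 1),
                (cx, cy - 2), (cx - 1, cy - 1), (cx - 1, cy + 1),
            ]
            keys = [corner(*p) for p in ring]
            for a, b in zip(keys, keys[1:] + keys[:1]):
                edges.add((min(a, b), max(a, b)))

    keys = sorted(corners, key=lambda k: (k[1], k[0]))
    ids = {k: i for i, k in enumerate(keys)}
    s = float(edge_length)
    pos = np.array([[X * math.sqrt(3) / 2 * s, Y * 0.5 * s] for X, Y in keys])
    edge_arr = np.array(sorted((min(ids[a], ids[b]), max(ids[a], ids[b]))
                               for a, b in edges))
    lengths = np.full(len(edge_arr), s)
    radii = np.full(len(edge_arr), radius)
    deg = np.zeros(len(keys), dtype=int)
    for i, j in edge_arr:
        deg[i] += 1
        deg[j] += 1
    roles = ["exit" if d < 3 else "normal" for d in deg]
    return TubularNetwork(
        np.arange(len(keys)), pos, roles, edge_arr, lengths, radii,
        {"builder": "honeycomb", "rows": rows, "cols": cols,
         "edge_length": s},
    )


def generate_er_like_network(n_nodes: int, target_mean_edge_length: float = 1.0,
                             seed: int = 0, radius: float = DEFAULT_RADIUS,
                             max_retries: int = 8) -> TubularNetwork:
    """Synthetic planar network with ER-like statistics.

    Vertices of a Voronoi diagram of uniformly random seed points, clipped to
    a disc, form a planar graph whose interior vertices have degree 3 — this
    matches the field statistics of peripheral-ER reconstructions (mean degree
    ≈ 3, irregular ~1 µm edges).  Coordinates are rescaled so the mean edge
    length equals ``target_mean_edge_length`` exactly.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be at least 10")
    if target_mean_edge_length <= 0:
        raise ValueError("target_mean_edge_length must be positive")
    rng = np.random.default_rng(seed)
    n_seeds = max(10, int(round(n_nodes * 0.55)))
    for attempt in range(max_retries):
        pts_r = np.sqrt(rng.random(n_seeds))
        pts_t = rng.random(n_seeds) * 2 * np.pi
        pts = np.column_stack([pts_r * np.cos(pts_t), pts_r * np.sin(pts_t)])
        vor = Voronoi(pts)
        keep = np.linalg.norm(vor.vertices, axis=1) < 1.0
        raw_edges = set()
        for rv in vor.ridge_vertices:
            a, b = rv
            if a >= 0 and b >= 0 and keep[a] and keep[b]:
                raw_edges.add((min(a, b), max(a, b)))
        g = nx.Graph(raw_edges)
        if g.number_of_nodes() == 0:
            n_seeds = int(n_seeds * 1.5)
            continue
        # drop degenerate micro-edges produced by near-cocircular seeds
        lens = {e: float(np.linalg.norm(vor.vertices[e[0]] - vor.vertices[e[1]]))
                for e in g.edges}
        mean_len = np.mean(list(lens.values()))
        g.remove_edges_from([e for e, l in lens.items() if l < 0.02 * mean_len])
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        g = g.subgraph(comps[0]).copy()
        degs = [d for _, d in g.degree]
        if g.number_of_nodes() < max(10, 0.5 * n_nodes) or not (
                2.5 <= np.mean(degs) <= 3.5):
            n_seeds = int(n_seeds * 1.3)
            continue
        nodes = sorted(g.nodes)
        remap = {v: i for i, v in enumerate(nodes)}
        pos = vor.vertices[nodes]
        edge_arr = np.array(sorted((min(remap[a], remap[b]), max(remap[a], remap[b]))
                                   for a, b in g.edges))
        lengths = np.linalg.norm(pos[edge_arr[:, 0]] - pos[edge_arr[:, 1]], axis=1)
        scale = target_mean_edge_length / lengths.mean()
        pos = pos * scale
        lengths = lengths * scale
        deg = np.zeros(len(nodes), dtype=int)
        for i, j in edge_arr:
            deg[i] += 1
            deg[j] += 1
        centre = pos.mean(axis=0)
        rdist = np.linalg.norm(pos - centre, axis=1)
        rim = rdist > 0.7 * rdist.max()
        roles = ["exit" if (deg[i] < 3 and rim[i]) else "normal"
                 for i in range(len(nodes))]
        if "exit" not in roles:
            roles[int(np.argmax(rdist))] = "exit"
        return TubularNetwork(
            np.arange(len(nodes)), pos, roles, edge_arr, lengths,
            np.full(len(edge_arr), radius),
            {"builder": "er_like_voronoi", "seed": seed,
             "target_mean_edge_length": target_mean_edge_length},
        )
    raise GenerationError(
        f"could not generate an ER-like network with ~{n_nodes} nodes "
        f"after {max_retries} attempts"
    )


def network_statistics(net: TubularNetwork) -> dict:
    """Summary record: N, E, mean degree, mean edge length, distributions."""
    deg = net.degrees()
    vals, counts = np.unique(deg, return_counts=True)
    hist, bin_edges = np.histogram(net.lengths, bins="auto")
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "mean_degree": float(deg.mean()),
        "mean_edge_length": float(net.lengths.mean()),
        "degree_distribution": {int(v): int(c) for v, c in zip(vals, counts)},
        "edge_length_histogram": {
            "counts": hist.tolist(),
            "bin_edges": bin_edges.tolist(),
        },
        "n_exit_nodes": int(len(net.exit_nodes)),
        "n_sheet_nodes": int(len(net.sheet_nodes)),
    }


# -- IO ----------------------------------------------------------------------

def _net_to_dict(net: TubularNetwork) -> dict:
    return {
        "nodes": [
            {"id": int(n), "x": float(x), "y": float(y), "role": role}
            for n, (x, y), role in zip(net.node_ids, net.pos, net.roles)
        ],
        "edges": [
            {"i": int(i), "j": int(j), "length": float(l), "radius": float(r)}
            for (i, j), l, r in zip(net.edges, net.lengths, net.radii)
        ],
        "metadata": net.metadata,
    }


def _net_from_dict(d: dict, context: str = "") -> TubularNetwork:
    try:
        nodes = d["nodes"]
        edges = d["edges"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{context}: missing 'nodes'/'edges' section") from exc
    try:
        ids = [int(n["id"]) for n in nodes]
        pos = [(float(n["x"]), float(n["y"])) for n in nodes]
        roles = [n.get("role", "normal") for n in nodes]
        pairs = [(int(e["i"]), int(e["j"])) for e in edges]
        lengths = [float(e["length"]) for e in edges]
        radii = [float(e.get("radius", DEFAULT_RADIUS)) for e in edges]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{context}: malformed node/edge record: {exc}") from exc
    try:
        return TubularNetwork(np.array(ids), np.array(pos), roles,
                              np.array(pairs), np.array(lengths),
                              np.array(radii), d.get("metadata", {}) or {})
    except NetworkError as exc:
        raise ParseError(f"{context}: {exc}") from exc


def write_network(net: TubularNetwork, path, fmt: str | None = None):
    """Write a network as edge-list JSON, a CSV pair, or GraphML."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "json":
        path.write_text(json.dumps(_net_to_dict(net), indent=1))
    elif fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "nodes.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "role"])
            for n, (x, y), role in zip(net.node_ids, net.pos, net.roles):
                w.writerow([int(n), float(x), float(y), role])
        with open(path / "edges.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["i", "j", "length", "radius"])
            for (i, j), l, r in zip(net.edges, net.lengths, net.radii):
                w.writerow([int(i), int(j), float(l), float(r)])
    elif fmt == "graphml":
        nx.write_graphml(net.graph(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path, fmt: str | None = None) -> TubularNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return _net_from_dict(d, str(path))
    if fmt == "csv":
        nodes, edges = [], []
        try:
            with open(path / "nodes.csv", newline="") as fh:
                for rec in csv.DictReader(fh):
                    nodes.append({"id": rec["id"], "x": rec["x"], "y": rec["y"],
                                  "role": rec.get("role", "normal")})
            with open(path / "edges.csv", newline="") as fh:
                for rec in csv.DictReader(fh):
                    edges.append({"i": rec["i"], "j": rec["j"],
                                  "length": rec["length"],
                                  "radius": rec.get("radius", DEFAULT_RADIUS)})
        except (KeyError, OSError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        return _net_from_dict({"nodes": nodes, "edges": edges}, str(path))
    if fmt == "graphml":
        g = nx.read_graphml(path, node_type=int)
        d = {
            "nodes": [{"id": n, "x": a["x"], "y": a["y"],
                       "role": a.get("role", "normal")}
                      for n, a in g.nodes(data=True)],
            "edges": [{"i": i, "j": j, "length": a["length"],
                       "radius": a.get("radius", DEFAULT_RADIUS)}
                      for i, j, a in g.edges(data=True)],
        }
        return _net_from_dict(d, str(path))
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    if path.suffix == ".json":
        return "json"
    if path.suffix == ".graphml":
        return "graphml"
    if path.suffix == "" or path.is_dir():
        return "csv"
    raise ValueError(f"cannot infer network format from {path}")
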