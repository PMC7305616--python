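"""Discretized attribution paths from a reference point x' to a sample x.

Four kinds, named by the space the trajectory lives in and its shape:

* ``O-L`` — straight line in the original feature space (classic IG).
* ``H-L`` — straight line between the latent codes z' = E(x') and z = E(x),
  decoded back to feature space, with linear end bridges absorbing the
  autoencoder's reconstruction error at the endpoints.
* ``O-N`` — shortest path through a k-nearest-neighbor graph of training
  points in feature space (Dijkstra on distance-weighted edges), linearly
  interpolated between waypoints. Keeps the path near observed data.
* ``H-N`` — the same graph construction in latent space, decoded, bridged.

Every path starts exactly at x' and ends exactly at x; ``alphas`` is the
normalized cumulative arc length of the discretized polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import networkx as nx
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .models import LatentCodec

__all__ = [
    "Path",
    "NeighborGraph",
    "linear_path",
    "latent_linear_path",
    "knn_graph",
    "neighbor_path",
    "write_path",
]

PATH_KINDS = ("O-L", "H-L", "O-N", "H-N")


@dataclass
class Path:
    points: np.ndarray  # (n_steps, p), from x' to x
    alphas: np.ndarray  # strictly increasing, 0 to 1
    kind: str
    bridge_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.kind not in PATH_KINDS:
            raise ValueError(f"unknown path kind {self.kind!r}")
        if self.points.shape[0] < 2:
            raise ValueError("a path needs at least 2 points")
        if not (np.all(np.diff(self.alphas) > 0)
                and self.alphas[0] == 0.0 and self.alphas[-1] == 1.0):
            raise ValueError("alphas must increase strictly from 0 to 1")

    @property
    def n_steps(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Total polyline arc length."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _alphas_from_arclength(points: np.ndarray) -> np.ndarray:
    n = points.shape[0]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0.0:
        return np.linspace(0.0, 1.0, n)
    cum = np.concatenate([[0.0], np.cumsum(seg)]) / total
    cum[-1] = 1.0  # guard against cumsum rounding
    # break exact ties from coincident points with an index ramp
    if np.any(np.diff(cum) <= 0):
        eps = 1e-12
        cum = (cum + eps * np.arange(n)) / (1.0 + eps * (n - 1))
        cum[0], cum[-1] = 0.0, 1.0
        if np.any(np.diff(cum) <= 0):  # pathological coincidences
            return np.linspace(0.0, 1.0, n)
    return cum


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total <= 0:
        return np.zeros(len(weights), dtype=int)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _points_along_polyline(waypoints: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points, keeping every waypoint.

    Interior points are allotted to segments proportionally to Euclidean
    segment length so integration error stays roughly uniform per unit
    length.
    """
    W = np.atleast_2d(np.asarray(waypoints, dtype=float))
    w = W.shape[0]
    if n < w:
        raise ValueError(f"need n={n} >= number of waypoints {w}")
    seg_len = np.linalg.norm(np.diff(W, axis=0), axis=1)
    interior = _largest_remainder(seg_len, n - w)
    chunks = []
    for i in range(w - 1):
        t = np.linspace(0.0, 1.0, interior[i] + 2)[:-1]  # keep start, drop end
        chunks.append(W[i] + t[:, None] * (W[i + 1] - W[i]))
    chunks.append(W[-1:])
    return np.vstack(chunks)


def linear_path(x_prime: np.ndarray, x: np.ndarray, n: int = 250) -> Path:
    """Straight-line path on a uniform grid (classic IG; 250 steps default)."""
    if n < 2:
        raise ValueError("need n >= 2 steps")
    x_prime = np.asarray(x_prime, dtype=float)
    x = np.asarray(x, dtype=float)
    t = np.linspace(0.0, 1.0, n)
    pts = x_prime + t[:, None] * (x - x_prime)
    pts[0], pts[-1] = x_prime, x
    return Path(pts, _alphas_from_arclength(pts), "O-L")


def _assemble_latent(
    x_prime: np.ndarray,
    x: np.ndarray,
    codec: LatentCodec,
    latent_waypoints: np.ndarray,
    n: int,
    kind: str,
) -> Path:
    """Decode a latent polyline and bridge its ends to the true endpoints.

    The decoded curve starts at D(E(x')) and ends at D(E(x)), which differ
    from x' and x by the reconstruction error; linear bridges close those
    gaps. Points are split between bridges and core proportionally to their
    lengths (core length estimated from a pilot decoding).
    """
    x_prime = np.asarray(x_prime, dtype=float)
    x = np.asarray(x, dtype=float)
    Wl = np.atleast_2d(latent_waypoints)
    r0 = codec.decode(Wl[:1])[0]
    r1 = codec.decode(Wl[-1:])[0]
    L1 = float(np.linalg.norm(r0 - x_prime))
    L2 = float(np.linalg.norm(x - r1))
    pilot = codec.decode(_points_along_polyline(Wl, max(Wl.shape[0], 64)))
    Lc = float(np.linalg.norm(np.diff(pilot, axis=0), axis=1).sum())

    nc_min = max(2, Wl.shape[0])
    if n < nc_min + 2:
        raise ValueError(f"need n >= {nc_min + 2} for this latent path")
    extra = _largest_remainder(np.array([L1, Lc, L2]), n - 2 - nc_min)
    n1, nc, n2 = int(extra[0]), nc_min + int(extra[1]), int(extra[2])

    core = codec.decode(_points_along_polyline(Wl, nc))
    t1 = np.linspace(0.0, 1.0, n1 + 2)[1:-1]
    bridge1 = x_prime + t1[:, None] * (core[0] - x_prime)
    t2 = np.linspace(0.0, 1.0, n2 + 2)[1:-1]
    bridge2 = core[-1] + t2[:, None] * (x - core[-1])
    pts = np.vstack([x_prime[None, :], bridge1, core, bridge2, x[None, :]])
    pts[0], pts[-1] = x_prime, x
    return Path(
        pts,
        _alphas_from_arclength(pts),
        kind,
        bridge_info={"start_length": L1, "end_length": L2, "core_length": Lc},
    )


def latent_linear_path(
    x_prime: np.ndarray, x: np.ndarray, codec: LatentCodec, n: int = 250
) -> Path:
    """Linear path between latent codes, decoded to feature space (H-L)."""
    if n < 4:
        raise ValueError("need n >= 4 (two endpoints plus a decoded core)")
    z = codec.encode(np.vstack([np.asarray(x_prime, dtype=float),
                                np.asarray(x, dtype=float)]))
    return _assemble_latent(x_prime, x, codec, z, n, "H-L")


@dataclass
class NeighborGraph:
    """k-NN graph over reference points, edges weighted by distance."""

    graph: nx.Graph
    coords: np.ndarray  # node coordinates in `space`
    k: int
    space: str = "original"  # or "latent"
    codec: LatentCodec | None = None

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


def knn_graph(
    points: np.ndarray,
    k: int,
    codec: LatentCodec | None = None,
    ensure_connected: bool = False,
) -> NeighborGraph:
    """Undirected k-nearest-neighbor graph on reference (training) points.

    Edge (a, b) exists if b is among a's k nearest or vice versa; weights
    are Euclidean distances. With a codec, the graph is built over the
    points' latent codes instead (for H-N paths). With ``ensure_connected``,
    disconnected components (which arise when reference classes are well
    separated) are joined through their single closest cross-component
    pair, so paths between classes remain well defined at moderate k.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if codec is not None:
        X = np.atleast_2d(codec.encode(X))
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k={k} < n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for a in range(n):
        for d, b in zip(dist[a, 1:], idx[a, 1:]):
            G.add_edge(a, int(b), weight=float(d))
    if ensure_connected:
        comps = [sorted(c) for c in nx.connected_components(G)]
        while len(comps) > 1:
            # bridge the first component to its nearest other component
            base = comps[0]
            best = None
            for other in comps[1:]:
                D = np.linalg.norm(
                    X[base][:, None, :] - X[other][None, :, :], axis=2
                )
                i, j = np.unravel_index(np.argmin(D), D.shape)
                if best is None or D[i, j] < best[0]:
                    best = (float(D[i, j]), base[i], other[j], other)
            d, a, b, other = best
            G.add_edge(a, b, weight=d)
            comps = [sorted(set(base) | set(other))] + [
                c for c in comps[1:] if c is not other
            ]
    return NeighborGraph(G, X, k, "latent" if codec is not None else "original",
                         codec)


def _waypoints_via_dijkstra(
    graph: NeighborGraph, e0: np.ndarray, e1: np.ndarray
) -> np.ndarray:
    """Add both endpoints to the graph and return shortest-path waypoints."""
    G = graph.graph.copy()
    coords = graph.coords
    k = min(graph.k, graph.n_nodes)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    for name, e, other in (("__src__", e0, e1), ("__dst__", e1, e0)):
        G.add_node(name)
        dist, idx = nn.kneighbors(e[None, :])
        for d, b in zip(dist[0], idx[0]):
            G.add_edge(name, int(b), weight=float(d))
        # the other endpoint competes as a candidate neighbor too, so a
        # short direct hop is never excluded by the graph construction
        d_direct = float(np.linalg.norm(e1 - e0))
        if d_direct <= dist[0].max():
            G.add_edge("__src__", "__dst__", weight=d_direct)
    try:
        node_seq = nx.shortest_path(G, "__src__", "__dst__", weight="weight")
    except nx.NetworkXNoPath:
        raise ValueError(
            "endpoints are disconnected in the neighbor graph; increase k"
        ) from None

    waypoints = [e0]
    for node in node_seq[1:-1]:
        waypoints.append(coords[node])
    waypoints.append(e1)
    return np.vstack(waypoints)


def neighbor_path(
    x_prime: np.ndarray,
    x: np.ndarray,
    graph: NeighborGraph,
    n: int = 250,
) -> Path:
    """Shortest-path trajectory through the neighbor graph (O-N or H-N).

    Both endpoints are linked to their k nearest graph nodes, the
    minimum-total-distance waypoint sequence is found by Dijkstra, and n
    points are spread along the waypoint polyline proportionally to segment
    lengths. For latent graphs the waypoints are found between z' and z and
    the polyline is decoded, with end bridges as in the H-L path.
    """
    x_prime = np.asarray(x_prime, dtype=float)
    x = np.asarray(x, dtype=float)
    if graph.space == "latent":
        assert graph.codec is not None
        z = graph.codec.encode(np.vstack([x_prime, x]))
        waypoints = _waypoints_via_dijkstra(graph, z[0], z[1])
        path = _assemble_latent(x_prime, x, graph.codec, waypoints, n, "H-N")
        path.bridge_info["waypoints"] = waypoints
        return path
    waypoints = _waypoints_via_dijkstra(graph, x_prime, x)
    pts = _points_along_polyline(waypoints, n)
    pts[0], pts[-1] = x_prime, x
    return Path(pts, _alphas_from_arclength(pts), "O-N",
                bridge_info={"n_waypoints": waypoints.shape[0],
                             "waypoints": waypoints})


def write_path(path: Path, file: str | FsPath) -> None:
    """TSV export: one row per step, alpha followed by the p coordinates."""
    file = FsPath(file)
    with file.open("w") as fh:
        fh.write(f"# kind={path.kind} n_steps={path.n_steps}\n")
        data = np.column_stack([path.alphas, path.points])
        np.savetxt(fh, data, delimiter="\t")
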