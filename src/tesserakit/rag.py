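"""Region adjacency graph (RAG) over tessera centroids.

One node per tile at its centroid; an edge whenever two tiles touch (share
face-adjacent voxel pairs) or, with ``bridge_gap``, come within a configured
distance of each other — recovering neighbours separated by the unmineralized
intertesseral gap.  The node degree is the tile's polygon class (a hexagonal
tile has six neighbours).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

__all__ = [
    "AdjacencyGraph",
    "centroids",
    "build_rag",
    "edit_rag",
    "neighbor_counts",
    "graph_from_tessellation",
]


class AdjacencyGraph:
    """Thin wrapper over an undirected networkx graph with an edit log.

    Nodes carry ``centroid`` (µm world coordinates) and optionally a
    ``boundary`` flag; edges carry ``contact`` — the number of face-adjacent
    voxel pairs (0 only for manually added or gap-bridged edges).
    """

    def __init__(self):
        self.g = nx.Graph()
        self.log: list = []

    def add_node(self, node_id: int, centroid, boundary: bool = False):
        self.g.add_node(int(node_id), centroid=np.asarray(centroid, float),
                        boundary=bool(boundary))

    def add_edge(self, a: int, b: int, contact: int = 0):
        if a == b:
            raise ValueError("self-edges are not allowed")
        if a not in self.g or b not in self.g:
            raise ValueError(f"edge ({a}, {b}) references a missing node")
        self.g.add_edge(int(a), int(b), contact=int(contact))

    def edges(self):
        return {tuple(sorted(e)) for e in self.g.edges}

    def centroid(self, node_id: int) -> np.ndarray:
        return self.g.nodes[node_id]["centroid"]

    def neighbors(self, node_id: int):
        return sorted(self.g.neighbors(node_id))

    def degree(self, node_id: int) -> int:
        return self.g.degree[node_id]

    def copy(self) -> "AdjacencyGraph":
        out = AdjacencyGraph()
        out.g = self.g.copy()
        out.log = list(self.log)
        return out

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "contact": d.get("contact", 0)}
            for a, b, d in self.g.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["a", "b", "contact"])

    def write_graphml(self, path):
        g = nx.Graph()
        for n, d in self.g.nodes(data=True):
            c = d["centroid"]
            g.add_node(n, cx=float(c[0]), cy=float(c[1]), cz=float(c[2]),
                       boundary=bool(d.get("boundary", False)))
        for a, b, d in self.g.edges(data=True):
            g.add_edge(a, b, contact=int(d.get("contact", 0)))
        nx.write_graphml(g, str(path))


def centroids(labels: LabelVolume) -> dict:
    """World-coordinate centroid of every tile: mean of member voxel centres."""
    ids = labels.ids()
    if len(ids) == 0:
        raise ValueError("no labels present")
    coms = ndimage.center_of_mass(labels.data > 0, labels.data, ids)
    v = labels.voxel_size
    return {int(i): (np.asarray(c) + 0.5) * v for i, c in zip(ids, coms)}


def _face_contacts(data: np.ndarray) -> dict:
    """Count face-adjacent (6-connectivity) voxel pairs per label pair."""
    contacts: dict = {}
    for axis in range(3):
        a = np.moveaxis(data, axis, 0)[:-1]
        b = np.moveaxis(data, axis, 0)[1:]
        m = (a > 0) & (b > 0) & (a != b)
        if not m.any():
            continue
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        pairs, counts = np.unique(np.column_stack([lo, hi]), axis=0,
                                  return_counts=True)
        for (x, y), c in zip(pairs, counts):
            key = (int(x), int(y))
            contacts[key] = contacts.get(key, 0) + int(c)
    return contacts


def build_rag(
    labels: LabelVolume,
    min_contact: int = 1,
    bridge_gap: float = 0.0,
    boundary_margin: float = 0.0,
) -> AdjacencyGraph:
    """Construct the RAG from an instance label volume.

    An edge joins two labels when they have at least ``min_contact``
    face-adjacent voxel pairs, or — with ``bridge_gap`` > 0 (µm) — when their
    supports come within ``bridge_gap`` of each other.  Gap bridging expands
    every label into the background by ``bridge_gap / 2`` (nearest-label
    Euclidean expansion) and takes the face adjacency of the expanded labels.

    ``boundary_margin`` (µm) flags nodes whose centroid lies within the
    margin of the volume faces; boundary tiles undercount their sides and are
    excluded from polygon-class statistics downstream.
    """
    data = labels.data
    v = labels.voxel_size
    graph = AdjacencyGraph()
    cents = centroids(labels)
    shape_um = np.asarray(data.shape) * v
    for node_id, c in cents.items():
        near_edge = bool(
            boundary_margin > 0
            and (np.any(c[:2] < boundary_margin)
                 or np.any(shape_um[:2] - c[:2] < boundary_margin))
        )
        graph.add_node(node_id, c, boundary=near_edge)

    contacts = _face_contacts(data)
    for (a, b), c in contacts.items():
        if c >= min_contact:
            graph.add_edge(a, b, contact=c)

    if bridge_gap > 0:
        bg = data == 0
        dist, (ix, iy, iz) = ndimage.distance_transform_edt(
            bg, sampling=v, return_indices=True
        )
        expanded = data[ix, iy, iz]
        expanded = np.where(dist <= bridge_gap / 2, expanded, 0)
        for (a, b), c in _face_contacts(expanded).items():
            if not graph.g.has_edge(a, b):
                graph.add_edge(a, b, contact=0)
    return graph


def edit_rag(graph: AdjacencyGraph, edits: list) -> AdjacencyGraph:
    """Apply ``("add", a, b)`` / ``("remove", a, b)`` edge edits in order."""
    out = graph.copy()
    for edit in edits:
        op, a, b = edit
        if a not in out.g or b not in out.g:
            raise ValueError(f"unknown node in edit {edit!r}")
        if op == "add":
            if a == b:
                raise ValueError("cannot add a self-edge")
            out.g.add_edge(a, b, contact=0)
        elif op == "remove":
            if not out.g.has_edge(a, b):
                raise ValueError(f"edge ({a}, {b}) does not exist")
            out.g.remove_edge(a, b)
        else:
            raise ValueError(f"unknown edit {op!r}")
        out.log.append((op, int(a), int(b)))
    return out


def graph_from_tessellation(tess) -> AdjacencyGraph:
    """RAG with nodes at the tessellation's seed points (ids start at 1).

    The exact counterpart of the RAG a perfect segmentation of the
    tessellation would produce; used as ground truth and as the direct route
    from a synthetic tessellation to graph-based morphometry.
    """
    graph = AdjacencyGraph()
    for i, seed in enumerate(tess.seeds):
        graph.add_node(i + 1, seed, boundary=bool(tess.boundary[i]))
    for (a, b) in tess.adjacency:
        graph.add_edge(a + 1, b + 1, contact=0)
    return graph


def neighbor_counts(graph: AdjacencyGraph, interior_only: bool = False) -> dict:
    """Node degree per tile — the tile's polygon class n."""
    out = {}
    for n, d in graph.g.nodes(data=True):
        if interior_only and d.get("boundary", False):
            continue
        out[int(n)] = graph.g.degree[n]
    return out
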