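"""Per-tessera morphometrics: thickness, width, volume, plane-based area,
and surface curvature.

All measures follow the bounding-box / graph-based definitions used for
tessellated cartilage: boxes are axis-aligned in the volume frame, the
thickness axis is found by summing the signed distance field along the six
cuboid-face normals from the tile centre (the outward direction accumulates
the largest positive distance), and the plane-based area is the shoelace
area of the projected triangle-fan centroids around the tile's node in the
region adjacency graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .rag import AdjacencyGraph
from .volumes import DistanceVolume, LabelVolume

__all__ = [
    "SurfaceMesh",
    "outward_axis",
    "tessera_thickness",
    "tessera_width",
    "tessera_volume",
    "plane_area",
    "smooth_surface_from_rag",
    "tessera_curvature",
    "mineralized_fraction",
    "measure_all",
]

# priority order for ties: +z > +y > +x > -z > -y > -x
_DIRECTIONS = np.array(
    [[0, 0, 1], [0, 1, 0], [1, 0, 0], [0, 0, -1], [0, -1, 0], [-1, 0, 0]]
)


@dataclass
class SurfaceMesh:
    """Smoothed surface mesh with per-vertex principal curvatures."""

    mesh: trimesh.Trimesh
    k1: np.ndarray
    k2: np.ndarray

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)


def _bbox(labels: LabelVolume, lab_id: int):
    objects = ndimage.find_objects((labels.data == lab_id).astype(np.uint8))
    if not objects or objects[0] is None:
        raise ValueError(f"unknown label id {lab_id}")
    return objects[0]


def outward_axis(
    labels: LabelVolume,
    signed_dist: DistanceVolume,
    lab_id: int,
    max_range: float | None = None,
) -> np.ndarray:
    """Outward-facing cuboid axis of a tile (one of ±x, ±y, ±z).

    From the tile centre, the signed distance field is sampled voxel by
    voxel along each of the six axis directions; the direction with the
    maximum summed distance faces outward (away from the skeleton, where
    positive distances accumulate).  ``max_range`` (µm) caps the ray length;
    by default rays run to the volume boundary, which suits tightly cropped
    scans — for shells enclosing a large hollow/unmineralized core a cap of
    a few shell thicknesses avoids far-field air dominating every ray.
    """
    data = labels.data
    support = np.argwhere(data == lab_id)
    if len(support) == 0:
        raise ValueError(f"unknown label id {lab_id}")
    centre = np.round(support.mean(axis=0)).astype(int)
    centre = np.clip(centre, 0, np.asarray(data.shape) - 1)
    return _outward_axis_from_centre(data.shape, signed_dist, centre, max_range)


def _outward_axis_from_centre(shape, signed_dist: DistanceVolume, centre,
                              max_range: float | None = None):
    """Axis-aligned ray sums of the signed distance from a voxel centre."""
    centre = np.clip(centre, 0, np.asarray(shape) - 1)
    cx, cy, cz = map(int, centre)
    sd = signed_dist.data
    n = sd.shape[0] + sd.shape[1] + sd.shape[2]
    if max_range is not None:
        n = max(1, int(round(max_range / signed_dist.voxel_size)))
    sums = np.array(
        [
            sd[cx, cy, cz + 1 : cz + 1 + n].sum(),
            sd[cx, cy + 1 : cy + 1 + n, cz].sum(),
            sd[cx + 1 : cx + 1 + n, cy, cz].sum(),
            sd[cx, cy, max(cz - n, 0) : cz][::-1].sum(),
            sd[cx, max(cy - n, 0) : cy, cz][::-1].sum(),
            sd[max(cx - n, 0) : cx, cy, cz][::-1].sum(),
        ]
    )
    return _DIRECTIONS[int(np.argmax(sums))].astype(float)


def tessera_thickness(labels: LabelVolume, lab_id: int, axis: np.ndarray) -> float:
    """Bounding-box side length (µm) along the thickness (outward) axis."""
    sl = _bbox(labels, lab_id)
    dim = int(np.argmax(np.abs(axis)))
    return (sl[dim].stop - sl[dim].start) * labels.voxel_size


def tessera_width(labels: LabelVolume, lab_id: int, axis: np.ndarray) -> float:
    """Largest non-thickness bounding-box side (µm).

    Taking the max of the two in-plane sides (rather than of all three)
    avoids conflating width and thickness for columnar tiles that are taller
    than wide.
    """
    sl = _bbox(labels, lab_id)
    dim = int(np.argmax(np.abs(axis)))
    sides = [(sl[d].stop - sl[d].start) for d in range(3) if d != dim]
    return max(sides) * labels.voxel_size


def tessera_volume(labels: LabelVolume, lab_id: int) -> float:
    """Member voxel count times voxel volume (µm³)."""
    n = int(np.count_nonzero(labels.data == lab_id))
    if n == 0:
        raise ValueError(f"unknown label id {lab_id}")
    return n * labels.voxel_size**3


def _fan_frame(centre: np.ndarray, nbrs: np.ndarray):
    """Fitted normal + in-plane axes for a neighbour fan around a centre."""
    offsets = nbrs - centre
    # initial normal: smallest principal direction of the neighbour cloud
    _, _, vt = np.linalg.svd(offsets - offsets.mean(axis=0))
    normal = vt[-1]
    t1 = vt[0] / np.linalg.norm(vt[0])
    t2 = np.cross(normal, t1)
    ang = np.arctan2(offsets @ t2, offsets @ t1)
    order = np.argsort(ang)
    ordered = nbrs[order]
    # refine: average of fan triangle normals, oriented consistently
    fan_normals = []
    m = len(ordered)
    for k in range(m):
        a, b = ordered[k] - centre, ordered[(k + 1) % m] - centre
        n = np.cross(a, b)
        nn = np.linalg.norm(n)
        if nn > 0:
            n = n / nn
            if n @ normal < 0:
                n = -n
            fan_normals.append(n)
    refined = np.mean(fan_normals, axis=0)
    refined = refined / np.linalg.norm(refined)
    t1 = np.cross(refined, ordered[0] - centre)
    t1 = np.cross(t1, refined)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(refined, t1)
    ang = np.arctan2(offsets @ t2, offsets @ t1)
    order = np.argsort(ang)
    return refined, t1, t2, nbrs[order]


def plane_area(graph: AdjacencyGraph, lab_id: int) -> float:
    """Plane-based tile area (µm²) from the adjacency graph.

    Neighbours are ordered angularly about the tile centre; the centroids of
    the consecutive fan triangles (centre, nbr_i, nbr_{i+1}) are projected
    onto the plane through the centre perpendicular to the fitted normal and
    the shoelace area of the resulting polygon is returned.  Tiles with
    fewer than three neighbours have no defined fan and raise.
    """
    nbr_ids = graph.neighbors(lab_id)
    if len(nbr_ids) < 3:
        raise ValueError(f"label {lab_id} has <3 neighbours; plane area undefined")
    centre = graph.centroid(lab_id)
    nbrs = np.array([graph.centroid(j) for j in nbr_ids], dtype=float)
    normal, t1, t2, ordered = _fan_frame(centre, nbrs)
    m = len(ordered)
    cents = np.array(
        [(centre + ordered[k] + ordered[(k + 1) % m]) / 3.0 for k in range(m)]
    )
    rel = cents - centre
    proj = rel - np.outer(rel @ normal, normal)
    x, y = proj @ t1, proj @ t2
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _graph_triangles(graph: AdjacencyGraph):
    """3-cliques of the RAG, the natural surface triangulation of the fan."""
    tris = set()
    for a, b in graph.g.edges:
        common = set(graph.g.neighbors(a)) & set(graph.g.neighbors(b))
        for c in common:
            tris.add(tuple(sorted((a, b, c))))
    return sorted(tris)


def smooth_surface_from_rag(graph: AdjacencyGraph, iterations: int = 10) -> SurfaceMesh:
    """Fit a finer, iteratively smoothed surface to the tile-centre mesh.

    The RAG's 3-cliques triangulate the coarse surface through the tile
    centres; the triangulation is midpoint-subdivided once and umbrella
    (Laplacian) smoothed ``iterations`` times.  Per-vertex principal
    curvatures are estimated by a local quadric fit over the vertex 2-ring.
    """
    node_ids = sorted(graph.g.nodes)
    index = {n: i for i, n in enumerate(node_ids)}
    verts = np.array([graph.centroid(n) for n in node_ids], dtype=float)
    tris = np.array(
        [[index[a], index[b], index[c]] for a, b, c in _graph_triangles(graph)],
        dtype=int,
    )
    if len(tris) == 0:
        raise ValueError("graph has no 3-cliques; not surface-triangulable")
    verts, tris = trimesh.remesh.subdivide(verts, tris)
    mesh = trimesh.Trimesh(vertices=verts, faces=tris, process=False)
    mesh.fix_normals()
    if not mesh.is_watertight:
        # open surface: orient away from the centroid so convexity reads H > 0
        out = mesh.vertices - mesh.vertices.mean(axis=0)
        if np.mean(np.einsum("ij,ij->i", out[mesh.faces[:, 0]],
                             mesh.face_normals)) < 0:
            mesh.invert()
    elif mesh.volume < 0:
        mesh.invert()

    # umbrella smoothing; boundary vertices held fixed so open sheets keep
    # their extent
    adj = [[] for _ in range(len(mesh.vertices))]
    for a, b in mesh.edges_unique:
        adj[a].append(b)
        adj[b].append(a)
    boundary_v = set()
    if not mesh.is_watertight:
        edge_count: dict = {}
        for f in mesh.faces:
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = tuple(sorted(map(int, e)))
                edge_count[key] = edge_count.get(key, 0) + 1
        for (a, b), c in edge_count.items():
            if c == 1:
                boundary_v.update((a, b))
    v = np.asarray(mesh.vertices, dtype=float).copy()
    movable = np.array([i not in boundary_v for i in range(len(v))])
    # shrink-compensated Laplacian (Taubin lambda/mu) so curved sheets keep
    # their radius while noise is smoothed away
    for _ in range(iterations):
        for factor in (0.5, -0.53):
            means = np.array([v[nb].mean(axis=0) if nb else v[i]
                              for i, nb in enumerate(adj)])
            v[movable] += factor * (means[movable] - v[movable])
    smoothed = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    k1, k2 = _principal_curvatures(smoothed, adj)
    return SurfaceMesh(mesh=smoothed, k1=k1, k2=k2)


def _principal_curvatures(mesh: trimesh.Trimesh, adj):
    """Quadric-fit principal curvatures over 2-ring neighbourhoods.

    Sign convention: convex surfaces with outward normals have positive
    curvature (sphere of radius R -> k1 = k2 = +1/R).
    """
    v = np.asarray(mesh.vertices, dtype=float)
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    n_vert = len(v)
    k1 = np.zeros(n_vert)
    k2 = np.zeros(n_vert)
    for i in range(n_vert):
        ring = set(adj[i])
        for j in list(ring):
            ring.update(adj[j])
        ring.discard(i)
        nbrs = np.fromiter(ring, dtype=int)
        if len(nbrs) < 5:
            continue
        n = normals[i]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(n, ref)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        rel = v[nbrs] - v[i]
        x, y, z = rel @ t1, rel @ t2, rel @ n
        # z = 1/2 a x^2 + b xy + 1/2 c y^2 + d x + e y  (linear terms absorb
        # normal estimation error)
        A = np.column_stack([0.5 * x**2, x * y, 0.5 * y**2, x, y])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        hess = np.array([[coef[0], coef[1]], [coef[1], coef[2]]])
        eig = np.linalg.eigvalsh(-hess)
        k1[i], k2[i] = eig[1], eig[0]
    return k1, k2


def tessera_curvature(surface: SurfaceMesh, centre) -> tuple:
    """Gaussian K = k1 k2 and mean H = (k1 + k2)/2 at the mesh vertex
    nearest the tessera centre."""
    verts = surface.vertices
    if len(verts) == 0:
        raise ValueError("empty mesh")
    idx = int(cKDTree(verts).query(np.asarray(centre, dtype=float))[1])
    return float(surface.k1[idx] * surface.k2[idx]), float(
        (surface.k1[idx] + surface.k2[idx]) / 2.0
    )


def mineralized_fraction(labels: LabelVolume, element_mask: np.ndarray) -> float:
    """Labeled (mineralized) voxels over element-mask voxels."""
    total = int(np.count_nonzero(element_mask))
    if total == 0:
        raise ValueError("empty element mask")
    return float(np.count_nonzero(labels.data > 0)) / total


def measure_all(
    labels: LabelVolume,
    signed_dist: DistanceVolume,
    graph: AdjacencyGraph,
    surface: SurfaceMesh | None = None,
    curved_K_threshold: float = np.inf,
    axis_max_range: float | None = None,
) -> pd.DataFrame:
    """Full per-tessera record table (one row per tile).

    Columns: centre coordinates, outward axis, thickness, width, volume,
    plane area (NaN for boundary/under-connected tiles), neighbour count,
    Gaussian/mean curvature (if a smoothed surface is supplied) and flags.
    """
    rows = []
    v = labels.voxel_size
    data = labels.data
    ids = labels.ids()
    counts = np.bincount(data.ravel())
    objects = ndimage.find_objects(data)
    coms = ndimage.center_of_mass(data > 0, data, ids)
    for lab_id, com in zip(ids, coms):
        lab_id = int(lab_id)
        sl = objects[lab_id - 1]
        axis = _outward_axis_from_centre(
            data.shape, signed_dist, np.round(com).astype(int), axis_max_range
        )
        dim = int(np.argmax(np.abs(axis)))
        sides = [(sl[d].stop - sl[d].start) * v for d in range(3)]
        boundary = bool(graph.g.nodes[lab_id].get("boundary", False)) \
            if lab_id in graph.g else True
        try:
            area = plane_area(graph, lab_id) if not boundary else float("nan")
        except ValueError:
            area = float("nan")
        n_nbr = graph.degree(lab_id) if lab_id in graph.g else 0
        if surface is not None and lab_id in graph.g:
            K, H = tessera_curvature(surface, graph.centroid(lab_id))
        else:
            K, H = float("nan"), float("nan")
        rows.append(
            {
                "id": lab_id,
                "axis_x": axis[0], "axis_y": axis[1], "axis_z": axis[2],
                "thickness_um": sides[dim],
                "width_um": max(s for d, s in enumerate(sides) if d != dim),
                "volume_um3": counts[lab_id] * v**3,
                "plane_area_um2": area,
                "n_neighbors": n_nbr,
                "gaussian_curvature": K,
                "mean_curvature": H,
                "boundary": boundary,
                "curved_region": bool(abs(K) > curved_K_threshold)
                if np.isfinite(K) else False,
            }
        )
    df = pd.DataFrame(rows).set_index("id")
    cents = {int(i): (np.asarray(c) + 0.5) * v for i, c in zip(ids, coms)}
    for ax_i, name in enumerate(("cx", "cy", "cz")):
        df[name] = [cents[i][ax_i] if i in cents else np.nan for i in df.index]
    return df
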