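"""Synthetic tessellations and voxelized shell phantoms with ground truth.

Real tessellated-cartilage data are µCT volumes of a thin mineralized shell
subdivided into tiles (tesserae) separated by narrow unmineralized gaps and
pocked by small cell lacunae.  This module builds stand-ins for those data
with complete ground truth — seed points, Voronoi cells, adjacency, per-tile
sizes and a voxelized grayscale/label pair — so the segmentation, graph and
morphometry stages can be validated without any download.

Surfaces are deliberately simple (plane/slab, sphere, cylinder): they emulate
curvature regimes of a skeletal element, not its anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import SphericalVoronoi, Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .volumes import GrayscaleVolume, LabelVolume

__all__ = [
    "SurfaceSpec",
    "Tessellation",
    "Phantom",
    "sample_hardcore_points",
    "voronoi_tessellation",
    "goldberg_tessellation",
    "voxelize_shell",
    "truth_report",
    "hexagonal_lattice_points",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Idealized substrate surface for a tessellation.

    kind : "plane", "slab-shell" (a plane destined for voxelization with
        finite thickness), "sphere" or "cylinder".
    extent : in-plane lengths in µm — (Lx, Ly) for planar kinds, (height,)
        for a cylinder; ignored for a sphere.
    radius : radius in µm for curved kinds.
    """

    kind: str
    extent: tuple = ()
    radius: float = 0.0

    def __post_init__(self):
        if self.kind not in ("plane", "slab-shell", "sphere", "cylinder"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent lengths must be positive")
        if self.kind in ("sphere", "cylinder") and self.radius <= 0:
            raise ValueError("curved surfaces need a positive radius")

    @property
    def is_planar(self) -> bool:
        return self.kind in ("plane", "slab-shell")


@dataclass
class Tessellation:
    """Combinatorial cell complex: the object topology/geometry ops consume.

    vertices : (V, 3) float array, µm.
    faces : list of vertex-index rings, one per cell, ordered around the cell.
    seeds : (F, 3) float array — the generating points (tile growth centres).
    adjacency : set of sorted (i, j) cell-index pairs sharing an edge.
    closed : True when the tessellation has no boundary (sphere).
    boundary : boolean flags, True for cells touching the domain boundary.
    """

    vertices: np.ndarray
    faces: list
    seeds: np.ndarray
    adjacency: set
    closed: bool
    boundary: np.ndarray
    surface: SurfaceSpec | None = None

    def __post_init__(self):
        for ring in self.faces:
            if len(set(ring)) < 3:
                raise ValueError("face ring must have >= 3 distinct vertices")

    @property
    def n_cells(self) -> int:
        return len(self.faces)

    def side_counts(self) -> np.ndarray:
        """Polygon class n of every cell (= ring length)."""
        return np.array([len(r) for r in self.faces])

    def cell_polygon(self, i: int) -> np.ndarray:
        return self.vertices[self.faces[i]]


@dataclass
class Phantom:
    """Voxelized shell phantom plus full ground truth."""

    gray: GrayscaleVolume
    truth_labels: LabelVolume
    voxel_size: float
    truth_table: pd.DataFrame
    truth_adjacency: set
    element_mask: np.ndarray
    lacunae_carved: dict = field(default_factory=dict)
    tessellation: Tessellation | None = None
    surface_kind: str = "slab-shell"
    shell_thickness: float = 0.0


# ---------------------------------------------------------------------------
# point processes


def _pairwise_ok(candidate, accepted, min_spacing, surface):
    if len(accepted) == 0 or min_spacing <= 0:
        return True
    pts = np.asarray(accepted)
    if surface.kind == "sphere":
        # geodesic distance on the sphere
        r = surface.radius
        cosang = np.clip(pts @ candidate / r**2, -1.0, 1.0)
        d = r * np.arccos(cosang)
    elif surface.kind == "cylinder":
        r = surface.radius
        du = np.abs(np.arctan2(pts[:, 1], pts[:, 0]) - np.arctan2(candidate[1], candidate[0]))
        du = np.minimum(du, 2 * np.pi - du) * r
        d = np.hypot(du, pts[:, 2] - candidate[2])
    else:
        d = np.linalg.norm(pts - candidate, axis=1)
    return bool(np.all(d >= min_spacing))


def sample_hardcore_points(
    surface: SurfaceSpec,
    n: int,
    min_spacing: float = 0.0,
    seed: int = 0,
    max_attempts_per_point: int = 500,
) -> np.ndarray:
    """Hard-core (minimum-spacing) random points on a surface.

    Dart throwing with a retry cap: candidates are drawn uniformly on the
    surface and rejected when closer than ``min_spacing`` (geodesic on the
    sphere, intrinsic on the cylinder, Euclidean on the plane) to an accepted
    point.  This emulates randomly placed tile growth centres subject to a
    minimum cell-cluster size.

    Returns an (n, 3) array of world coordinates in µm (z = 0 on planes).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    rng = np.random.default_rng(seed)
    accepted: list = []
    budget = max_attempts_per_point * n
    attempts = 0
    while len(accepted) < n and attempts < budget:
        attempts += 1
        if surface.is_planar:
            lx, ly = surface.extent[:2]
            c = np.array([rng.uniform(0, lx), rng.uniform(0, ly), 0.0])
        elif surface.kind == "sphere":
            v = rng.normal(size=3)
            c = surface.radius * v / np.linalg.norm(v)
        else:  # cylinder
            theta = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(0, surface.extent[0])
            c = np.array(
                [surface.radius * np.cos(theta), surface.radius * np.sin(theta), z]
            )
        if _pairwise_ok(c, accepted, min_spacing, surface):
            accepted.append(c)
    if len(accepted) < n:
        raise RuntimeError(
            f"hard-core packing infeasible: placed {len(accepted)}/{n} points "
            f"at spacing {min_spacing} after {budget} attempts"
        )
    return np.asarray(accepted)


def hexagonal_lattice_points(nx: int, ny: int, spacing: float = 1.0) -> np.ndarray:
    """Triangular-lattice points (nearest-neighbour distance = spacing).

    The Voronoi diagram of this lattice is the regular hexagonal tiling, the
    standard analytic oracle for planar cell geometry.
    """
    pts = []
    for j in range(ny):
        for i in range(nx):
            x = (i + 0.5 * (j % 2)) * spacing
            y = j * spacing * np.sqrt(3) / 2
            pts.append((x, y, 0.0))
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# tessellations


def _dedup_vertices(coords, tol):
    """Merge near-coincident vertices; return (unique_array, index_map)."""
    coords = np.asarray(coords, dtype=float)
    key = np.round(coords / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return coords[first], inverse


def _ring_from_polygon(poly: Polygon, vert_list, vert_index, tol):
    ring = []
    xy = np.asarray(poly.exterior.coords)[:-1]  # drop closing duplicate
    if Polygon(xy).exterior.is_ccw is False:
        xy = xy[::-1]
    for p in xy:
        k = (round(p[0] / tol), round(p[1] / tol))
        if k not in vert_index:
            vert_index[k] = len(vert_list)
            vert_list.append((p[0], p[1], 0.0))
        idx = vert_index[k]
        if not ring or ring[-1] != idx:
            ring.append(idx)
    if len(ring) > 1 and ring[0] == ring[-1]:
        ring.pop()
    return ring


def _planar_voronoi(points2d, bbox, surface):
    """Clipped planar Voronoi; returns a Tessellation in the z=0 plane.

    Seeds are mirrored across each box edge before triangulating, so every
    real cell is bounded and clipped exactly at the box (the bisector of a
    seed and its own mirror IS the box edge).
    """
    pts = np.asarray(points2d, dtype=float)
    n = len(pts)
    x0, y0, x1, y1 = bbox
    tol = 1e-9 * max(x1 - x0, y1 - y0, 1.0)
    mirrors = [
        np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),
    ]
    try:
        vor = Voronoi(np.vstack([pts] + mirrors))
    except Exception as exc:
        raise ValueError(f"degenerate planar configuration: {exc}") from exc

    vert_list: list = []
    vert_index: dict = {}
    faces = []
    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError(f"degenerate (unbounded) Voronoi cell for seed {i}")
        cell = Polygon(vor.vertices[region])
        if cell.area <= 0:
            raise ValueError(f"degenerate Voronoi cell for seed {i}")
        bx = cell.bounds
        if (bx[0] < x0 + tol or bx[1] < y0 + tol
                or bx[2] > x1 - tol or bx[3] > y1 - tol):
            boundary[i] = True
        faces.append(_ring_from_polygon(cell, vert_list, vert_index, tol))

    adjacency = set()
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if a < n and b < n and a != b:
            if -1 not in rv and len(rv) == 2:
                length = np.linalg.norm(vor.vertices[rv[0]] - vor.vertices[rv[1]])
                if length <= tol:
                    continue
            adjacency.add((min(a, b), max(a, b)))

    return Tessellation(
        vertices=np.asarray(vert_list),
        faces=faces,
        seeds=np.column_stack([pts, np.zeros(n)]),
        adjacency=adjacency,
        closed=False,
        boundary=boundary,
        surface=surface,
    )


def _spherical_voronoi(points, surface):
    n = len(points)
    if n < 4:
        raise ValueError("spherical Voronoi needs >= 4 non-degenerate points")
    r = surface.radius
    try:
        sv = SphericalVoronoi(points, radius=r, center=np.zeros(3))
    except Exception as exc:  # cospherical degeneracy surfaces from qhull
        raise ValueError(f"degenerate spherical configuration: {exc}") from exc
    sv.sort_vertices_of_regions()
    verts, inverse = _dedup_vertices(sv.vertices, tol=1e-9 * r)
    faces = []
    for region in sv.regions:
        ring = []
        for v in region:
            idx = int(inverse[v])
            if not ring or ring[-1] != idx:
                ring.append(idx)
        if len(ring) > 1 and ring[0] == ring[-1]:
            ring.pop()
        faces.append(ring)
    edge_faces: dict = {}
    for fi, ring in enumerate(faces):
        for k in range(len(ring)):
            e = tuple(sorted((ring[k], ring[(k + 1) % len(ring)])))
            edge_faces.setdefault(e, set()).add(fi)
    adjacency = set()
    for fs in edge_faces.values():
        if len(fs) == 2:
            a, b = sorted(fs)
            adjacency.add((a, b))
    return Tessellation(
        vertices=verts,
        faces=faces,
        seeds=np.asarray(points),
        adjacency=adjacency,
        closed=True,
        boundary=np.zeros(n, dtype=bool),
        surface=surface,
    )


def _cylindrical_voronoi(points, surface):
    """Voronoi on a cylinder via the unrolled plane.

    The seam is handled with periodic copies in the unrolled coordinate;
    the open ends are handled by mirror copies across v = 0 and v = h, so
    end cells are clipped exactly at the rims.
    """
    r, h = surface.radius, surface.extent[0]
    n = len(points)
    theta = np.mod(np.arctan2(points[:, 1], points[:, 0]), 2 * np.pi)
    u = r * theta
    v = points[:, 2]
    circ = 2 * np.pi * r
    real = [np.column_stack([u + s, v]) for s in (-circ, 0.0, circ)]
    ghosts = []
    for block in real:
        ghosts.append(np.column_stack([block[:, 0], -block[:, 1]]))
        ghosts.append(np.column_stack([block[:, 0], 2 * h - block[:, 1]]))
    vor = Voronoi(np.vstack(real + ghosts))
    tol = 1e-9 * max(circ, h)
    vert_list: list = []
    vert_index: dict = {}
    faces = []
    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        idx = n + i  # central real copy
        region = vor.regions[vor.point_region[idx]]
        if -1 in region or len(region) == 0:
            raise ValueError(f"degenerate cylindrical cell for seed {i}")
        cell = Polygon(vor.vertices[region])
        if cell.bounds[1] < tol or cell.bounds[3] > h - tol:
            boundary[i] = True
        faces.append(_ring_from_polygon(cell, vert_list, vert_index, tol))
    adjacency = set()
    n_real = 3 * n
    for (a, b) in vor.ridge_points:
        if a >= n_real or b >= n_real:
            continue  # ghost (rim mirror) contact, not a real neighbour
        central = (n <= a < 2 * n) or (n <= b < 2 * n)
        ia, ib = a % n, b % n
        if central and ia != ib:
            adjacency.add((min(ia, ib), max(ia, ib)))
    verts2d = np.asarray(vert_list)
    verts3d = np.column_stack(
        [r * np.cos(verts2d[:, 0] / r), r * np.sin(verts2d[:, 0] / r), verts2d[:, 1]]
    )
    return Tessellation(
        vertices=verts3d,
        faces=faces,
        seeds=np.asarray(points),
        adjacency=adjacency,
        closed=False,
        boundary=boundary,
        surface=surface,
    )


def voronoi_tessellation(points: np.ndarray, surface: SurfaceSpec) -> Tessellation:
    """Voronoi tessellation of a surface from seed points.

    Each surface point belongs to the cell of its nearest seed — the
    equipartitioning of space between neighbouring growth centres.  Planar
    diagrams are clipped to the extent box and boundary cells flagged;
    spherical diagrams are closed.
    """
    points = np.asarray(points, dtype=float)
    if len(points) >= 2:
        d, _ = cKDTree(points).query(points, k=2)
        if np.min(d[:, 1]) <= 1e-12:
            raise ValueError("degenerate configuration: coincident seed points")
    if surface.is_planar:
        if len(points) < 2:
            raise ValueError("planar Voronoi needs >= 2 points")
        lx, ly = surface.extent[:2]
        return _planar_voronoi(points[:, :2], (0.0, 0.0, lx, ly), surface)
    if surface.kind == "sphere":
        return _spherical_voronoi(points, surface)
    return _cylindrical_voronoi(points, surface)


def goldberg_tessellation(frequency: int = 0) -> Tessellation:
    """Closed trivalent pentagon/hexagon tiling of the sphere.

    Built as the dual of a ``frequency``-times subdivided icosahedron
    projected to the unit sphere: 12 pentagons (at the icosahedral vertices)
    and otherwise hexagons, the fullerene-like family.  frequency=0 gives the
    dodecahedron.
    """
    import trimesh

    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=frequency, radius=1.0)
    V = np.asarray(mesh.vertices)
    F = np.asarray(mesh.faces)
    centroids = V[F].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)

    incident: list = [[] for _ in range(len(V))]
    for fi, tri in enumerate(F):
        for vtx in tri:
            incident[vtx].append(fi)

    faces = []
    for vi in range(len(V)):
        nrm = V[vi] / np.linalg.norm(V[vi])
        # orthonormal tangent frame for angular ordering of incident centroids
        ref = np.array([1.0, 0.0, 0.0])
        if abs(nrm @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(nrm, ref)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)
        tri_ids = incident[vi]
        c = centroids[tri_ids]
        ang = np.arctan2(c @ t2, c @ t1)
        order = np.argsort(ang)
        faces.append([tri_ids[k] for k in order])

    edge_set = {tuple(sorted((int(a), int(b)))) for tri in F
                for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))}
    adjacency = set(edge_set)
    return Tessellation(
        vertices=centroids,
        faces=faces,
        seeds=V.copy(),
        adjacency=adjacency,
        closed=True,
        boundary=np.zeros(len(V), dtype=bool),
        surface=SurfaceSpec("sphere", radius=1.0),
    )


# ---------------------------------------------------------------------------
# voxelization


def voxelize_shell(
    tess: Tessellation,
    shell_thickness: float,
    gap_width: float,
    voxel: float,
    lacunae: tuple = (0, 0.0),
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int = 0,
    core_depth: float = 25.0,
    air_depth: float = 75.0,
    max_voxels: int = 400_000_000,
) -> Phantom:
    """Voxelize a tessellated shell into a grayscale + truth-label phantom.

    Each shell voxel is assigned to its nearest tile seed unless it lies
    within ``gap_width / 2`` of a cell boundary (then background 0, the
    unmineralized gap).  ``lacunae = (count, radius_um)`` carves that many
    spherical voids per tile, recorded in the returned truth.  The grayscale
    channel is the binary labelled support (contrast 1.0) after a Gaussian
    blur of ``blur_sigma`` µm and additive Gaussian noise of sd ``noise_sd``.

    Planar tessellations become a flat slab shell with ``core_depth`` µm of
    unmineralized core below and ``air_depth`` µm of air above; spherical
    ones become a hollow spherical shell.
    """
    if shell_thickness < 2 * voxel:
        raise ValueError("shell_thickness must be >= 2 voxels")
    if gap_width < 0:
        raise ValueError("gap_width must be >= 0")
    surface = tess.surface
    rng = np.random.default_rng(seed)
    seeds = tess.seeds

    if surface is not None and surface.is_planar:
        lx, ly = surface.extent[:2]
        nx, ny = int(round(lx / voxel)), int(round(ly / voxel))
        t_vox = int(round(shell_thickness / voxel))
        z0 = int(round(core_depth / voxel))
        nz = z0 + t_vox + int(round(air_depth / voxel))
        if nx * ny * nz > max_voxels:
            raise ValueError(
                f"voxel grid {nx}x{ny}x{nz} exceeds cap of {max_voxels} voxels"
            )
        labels = np.zeros((nx, ny, nz), dtype=np.int32)
        xs = (np.arange(nx) + 0.5) * voxel
        ys = (np.arange(ny) + 0.5) * voxel
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        cols = np.column_stack([gx.ravel(), gy.ravel()])
        tree = cKDTree(seeds[:, :2])
        dd, ii = tree.query(cols, k=min(2, len(seeds)))
        if len(seeds) == 1:
            owner = np.zeros(len(cols), dtype=int)
            in_gap = np.zeros(len(cols), dtype=bool)
        else:
            owner = ii[:, 0]
            in_gap = (dd[:, 1] - dd[:, 0]) < gap_width
        col_label = np.where(in_gap, 0, owner + 1).reshape(nx, ny).astype(np.int32)
        labels[:, :, z0 : z0 + t_vox] = col_label[:, :, None]
        element_mask = np.zeros((nx, ny, nz), dtype=bool)
        element_mask[:, :, : z0 + t_vox] = True
    elif surface is not None and surface.kind == "sphere":
        r = surface.radius
        # air_depth sets the outside padding; for unambiguous outward-axis
        # detection it should exceed the core diameter 2r
        half = r + shell_thickness / 2 + max(air_depth, 3 * voxel)
        ngrid = int(np.ceil(2 * half / voxel))
        if ngrid**3 > max_voxels:
            raise ValueError(f"voxel grid {ngrid}^3 exceeds cap of {max_voxels} voxels")
        ax = (np.arange(ngrid) + 0.5) * voxel - half
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        rad = np.sqrt(gx**2 + gy**2 + gz**2)
        shell = np.abs(rad - r) <= shell_thickness / 2
        labels = np.zeros(shell.shape, dtype=np.int32)
        pts = np.column_stack([gx[shell], gy[shell], gz[shell]])
        tree = cKDTree(seeds)
        dd, ii = tree.query(pts, k=min(2, len(seeds)))
        if len(seeds) == 1:
            lab = np.ones(len(pts), dtype=np.int32)
        else:
            lab = np.where((dd[:, 1] - dd[:, 0]) < gap_width, 0, ii[:, 0] + 1)
        labels[shell] = lab
        element_mask = rad <= r + shell_thickness / 2
    else:
        raise NotImplementedError("voxelization supports planar and spherical shells")

    # carve lacunae strictly inside tiles (cell spaces within tesserae)
    lac_count, lac_radius = lacunae
    carved: dict = {}
    if lac_count > 0 and lac_radius > 0:
        fg = labels > 0
        edt = ndimage.distance_transform_edt(fg, sampling=voxel)
        # two-voxel clearance keeps carved voids strictly interior (no face
        # adjacency with gap or outside background), and a margin from the
        # volume faces keeps them from poking through the array border
        safe = edt > (lac_radius + 2 * voxel)
        m = int(np.ceil(lac_radius / voxel)) + 2
        edge = np.ones_like(safe)
        edge[m:-m, m:-m, m:-m] = False
        safe &= ~edge
        r_vox = lac_radius / voxel
        safe_idx = np.argwhere(safe)
        safe_lab = labels[safe]
        order = np.argsort(safe_lab, kind="stable")
        safe_idx, safe_lab = safe_idx[order], safe_lab[order]
        starts = np.searchsorted(safe_lab, np.arange(1, labels.max() + 2))
        for lab_id in np.unique(labels[labels > 0]):
            cand = safe_idx[starts[lab_id - 1] : starts[lab_id]]
            if len(cand) == 0:
                carved[int(lab_id)] = 0
                continue
            pick = cand[rng.choice(len(cand), size=min(lac_count, len(cand)),
                                   replace=False)]
            n_carved = 0
            for centre in pick:
                lo = np.maximum(centre - int(np.ceil(r_vox)) - 1, 0)
                hi = np.minimum(centre + int(np.ceil(r_vox)) + 2, labels.shape)
                sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                ix, iy, iz = np.meshgrid(
                    *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
                )
                inside = ((ix - centre[0]) ** 2 + (iy - centre[1]) ** 2
                          + (iz - centre[2]) ** 2) <= r_vox**2
                n_carved += int(np.count_nonzero(inside & (sub > 0)))
                sub[inside] = 0
            carved[int(lab_id)] = n_carved

    # grayscale: blurred, noised binary support of the labels
    gray = (labels > 0).astype(np.float32)
    if blur_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=blur_sigma / voxel)
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape).astype(np.float32)

    label_vol = LabelVolume(labels, voxel)
    table = _truth_table(label_vol, tess, shell_thickness, surface)
    truth_adjacency = {(i + 1, j + 1) for (i, j) in tess.adjacency}
    return Phantom(
        gray=GrayscaleVolume(gray.astype(np.float32), voxel),
        truth_labels=label_vol,
        voxel_size=voxel,
        truth_table=table,
        truth_adjacency=truth_adjacency,
        element_mask=element_mask,
        lacunae_carved=carved,
        tessellation=tess,
        surface_kind=surface.kind,
        shell_thickness=shell_thickness,
    )


def _truth_table(label_vol: LabelVolume, tess, shell_thickness, surface):
    labels = label_vol.data
    v = label_vol.voxel_size
    ids = label_vol.ids()
    planar = surface is not None and surface.is_planar
    objects = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel())
    coms = ndimage.center_of_mass(labels > 0, labels, ids)
    neighbor_count = {i: 0 for i in ids}
    for (a, b) in tess.adjacency:
        # only neighbours that materialized as voxels count
        if (a + 1) in neighbor_count and (b + 1) in neighbor_count:
            neighbor_count[a + 1] += 1
            neighbor_count[b + 1] += 1
    rows = []
    for lab_id, com in zip(ids, coms):
        sl = objects[lab_id - 1]
        if planar:
            thick = (sl[2].stop - sl[2].start) * v
        else:
            thick = shell_thickness
        rows.append(
            {
                "id": int(lab_id),
                "volume_um3": float(counts[lab_id]) * v**3,
                "thickness_um": float(thick),
                "cx": (com[0] + 0.5) * v,
                "cy": (com[1] + 0.5) * v,
                "cz": (com[2] + 0.5) * v,
                "n_neighbors": neighbor_count[int(lab_id)],
            }
        )
    return pd.DataFrame(rows).set_index("id")


def truth_report(phantom: Phantom) -> pd.DataFrame:
    """Recompute the per-tile truth morphometrics from the truth labels.

    One row per tile: volume (µm³), thickness (µm), world-coordinate centre
    and neighbour count; guaranteed consistent with a recount of the label
    volume (this IS a recount).
    """
    return _truth_table(
        phantom.truth_labels,
        phantom.tessellation,
        phantom.shell_thickness,
        phantom.tessellation.surface if phantom.tessellation else None,
    )
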