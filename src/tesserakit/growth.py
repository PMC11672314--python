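"""Two-scenario growth simulator for an expanding tessellation.

The substrate (unmineralized cartilage core) expands uniformly, pulling
rigid mineralized tiles apart and opening per-neighbour gaps g_ij.  Mineral
apposition then advances each tile's front toward each neighbour:

* constant rule — every front advances by the same increment δ (clipped at
  contact), which cannot close the larger gaps that open next to larger
  tiles and leaves uncovered regions where new tiles would have to be
  inserted;
* proportional rule — each front advances by k·g_ij/2, equal on both ends of
  each fiber (equal fiber force).  Larger tiles then accrete more total new
  area per cycle, the tiling stays complete with a fixed tile count, and any
  starting configuration converges toward the Voronoi tessellation of its
  growth centres.

Tiles are intersections of half-planes at per-neighbour front offsets, which
makes "apposition on a face" a scalar update and overlap-freedom provable:
fronts never advance past the gap midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .synthetic import Tessellation

__all__ = [
    "GrowthState",
    "GrowthTrajectory",
    "init_state",
    "chain_state",
    "expand_substrate",
    "appose_constant",
    "appose_proportional",
    "tile_polygon",
    "tile_areas",
    "coverage_fraction",
    "propose_new_tiles",
    "voronoi_deviation",
    "run_cycles",
]

_BIG = 1e7  # half-plane construction extent safety factor, µm


@dataclass
class GrowthState:
    """Simulator state in the current (expanded) substrate frame.

    centers0 : (N, 2) initial seed centres, µm.  Current centres are
        ``lam_cum * centers0`` (uniform expansion about the origin).
    fronts : directed map (i, j) -> f_ij, the distance from centre i to its
        mineral front toward neighbour j.  Gap g_ij = d_ij − f_ij − f_ji ≥ 0.
    walls : per-tile list of substrate-boundary half-planes
        ``[unit normal u, initial support h0, front f]``; the wall itself
        sits at ``lam_cum * h0`` from the current centre.
    substrate0 : initial substrate outline (shapely polygon) or None.
    """

    centers0: np.ndarray
    lam_cum: float
    fronts: dict
    d0: dict
    walls: dict
    substrate0: Polygon | None = None
    step: int = 0

    @property
    def n_tiles(self) -> int:
        return len(self.centers0)

    @property
    def centers(self) -> np.ndarray:
        return self.lam_cum * self.centers0

    def pairs(self):
        return sorted(self.d0)

    def neighbor_map(self) -> dict:
        nbrs: dict = {i: [] for i in range(self.n_tiles)}
        for (i, j) in self.d0:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def distance(self, i: int, j: int) -> float:
        return self.lam_cum * self.d0[(min(i, j), max(i, j))]

    def gap(self, i: int, j: int) -> float:
        return self.distance(i, j) - self.fronts[(i, j)] - self.fronts[(j, i)]

    def wall_gap(self, i: int, w: int) -> float:
        u, h0, f = self.walls[i][w]
        return self.lam_cum * h0 - f

    def copy(self) -> "GrowthState":
        return GrowthState(
            centers0=self.centers0.copy(),
            lam_cum=self.lam_cum,
            fronts=dict(self.fronts),
            d0=dict(self.d0),
            walls={i: [[u.copy(), h0, f] for (u, h0, f) in ws]
                   for i, ws in self.walls.items()},
            substrate0=self.substrate0,
            step=self.step,
        )

    def check_invariants(self, tol: float = 1e-9):
        for (i, j) in self.pairs():
            g = self.gap(i, j)
            if g < -tol * max(1.0, self.distance(i, j)):
                raise AssertionError(f"overlap on fiber ({i}, {j}): gap {g}")
        for fr in self.fronts.values():
            if fr <= 0:
                raise AssertionError("non-positive front offset")


@dataclass
class GrowthTrajectory:
    """Per-cycle summaries of a growth run."""

    table: pd.DataFrame
    areas: list = field(default_factory=list)  # tile-area array per cycle

    def __len__(self) -> int:
        return len(self.table)


def init_state(tess: Tessellation, fill_fraction: float = 1.0) -> GrowthState:
    """Initialize from a planar tessellation with each tile set to its
    Voronoi cell shrunk toward its centre by sqrt(fill_fraction).

    Shrinking a convex cell scales every support distance, so the front
    toward neighbour j starts at sqrt(fill_fraction) * d_ij / 2 and wall
    fronts at sqrt(fill_fraction) * h0.
    """
    if not (0 < fill_fraction <= 1):
        raise ValueError("fill_fraction must be in (0, 1]")
    if tess.closed or tess.surface is None or not tess.surface.is_planar:
        raise ValueError("growth simulation requires a planar tessellation")
    s = np.sqrt(fill_fraction)
    centers = tess.seeds[:, :2].astype(float)
    fronts: dict = {}
    d0: dict = {}
    for (i, j) in tess.adjacency:
        d = float(np.linalg.norm(centers[j] - centers[i]))
        d0[(i, j)] = d
        fronts[(i, j)] = s * d / 2
        fronts[(j, i)] = s * d / 2

    lx, ly = tess.surface.extent[:2]
    tol = 1e-6 * max(lx, ly)
    walls: dict = {i: [] for i in range(len(centers))}
    for i, ring in enumerate(tess.faces):
        poly = tess.vertices[ring][:, :2]
        c = centers[i]
        m = len(poly)
        for k in range(m):
            a, b = poly[k], poly[(k + 1) % m]
            on_box = all(
                abs(p[0]) < tol or abs(p[0] - lx) < tol
                or abs(p[1]) < tol or abs(p[1] - ly) < tol
                for p in (a, b)
            )
            if not on_box:
                continue
            mid = (a + b) / 2
            edge = b - a
            u = np.array([edge[1], -edge[0]])
            nrm = np.linalg.norm(u)
            if nrm == 0:
                continue
            u = u / nrm
            if (mid - c) @ u < 0:
                u = -u
            h0 = float((mid - c) @ u)
            walls[i].append([u, h0, s * h0])
    return GrowthState(
        centers0=centers,
        lam_cum=1.0,
        fronts=fronts,
        d0=d0,
        walls=walls,
        substrate0=box(0.0, 0.0, lx, ly),
    )


def chain_state(positions, front: float) -> GrowthState:
    """1-D chain of tiles: an analytically checkable reduction.

    ``positions`` are centre coordinates on a line; consecutive tiles are
    fiber-linked with equal initial fronts.  Gap/apposition arithmetic is
    shared with the 2-D simulator; polygon operations do not apply.
    """
    pos = np.asarray(positions, dtype=float)
    centers = np.column_stack([pos, np.zeros(len(pos))])
    fronts: dict = {}
    d0: dict = {}
    for i in range(len(pos) - 1):
        d = float(pos[i + 1] - pos[i])
        d0[(i, i + 1)] = d
        fronts[(i, i + 1)] = front
        fronts[(i + 1, i)] = front
    return GrowthState(
        centers0=centers, lam_cum=1.0, fronts=fronts, d0=d0,
        walls={i: [] for i in range(len(pos))},
    )


def expand_substrate(state: GrowthState, lam: float) -> GrowthState:
    """Uniform substrate expansion by factor λ > 1.

    Centres (and substrate walls) scale; the rigid mineral fronts do not, so
    every fiber gap grows by exactly (λ − 1) · d_ij — larger neighbouring
    tiles open larger absolute gaps.
    """
    if lam <= 1:
        raise ValueError("expansion factor must exceed 1")
    out = state.copy()
    out.lam_cum *= lam
    return out


def appose_constant(state: GrowthState, delta: float) -> GrowthState:
    """Advance every front by δ, clipped at contact (no overlap created)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = state.copy()
    for (i, j) in out.pairs():
        g = out.gap(i, j)
        adv = min(delta, g / 2)
        out.fronts[(i, j)] += adv
        out.fronts[(j, i)] += adv
    for i, ws in out.walls.items():
        for w in range(len(ws)):
            g = out.wall_gap(i, w)
            ws[w][2] += min(delta, g)
    return out


def appose_proportional(state: GrowthState, k: float) -> GrowthState:
    """Advance each front by k·g_ij/2, equal on both ends of each fiber.

    The strain-driven rule: gap size sets the apposition increment, so
    larger tiles (with larger gaps opening beside them) accrete more total
    new area per cycle.  Wall fronts advance by k·g (single front).
    """
    if not (0 < k <= 1):
        raise ValueError("k must be in (0, 1]")
    out = state.copy()
    for (i, j) in out.pairs():
        adv = k * out.gap(i, j) / 2
        out.fronts[(i, j)] += adv
        out.fronts[(j, i)] += adv
    for i, ws in out.walls.items():
        for w in range(len(ws)):
            ws[w][2] += k * out.wall_gap(i, w)
    return out


def tile_polygon(state: GrowthState, i: int, nbrs: list | None = None) -> Polygon:
    """Tile i as the intersection of its front half-planes."""
    c = state.centers[i]
    if nbrs is None:
        nbrs = state.neighbor_map()[i]
    fr = [state.fronts[(i, j)] for j in nbrs]
    extent = 4 * max(fr) if fr else _BIG
    poly = box(c[0] - extent, c[1] - extent, c[0] + extent, c[1] + extent)
    for j in nbrs:
        u = state.centers[j] - c
        u = u / np.linalg.norm(u)
        poly = poly.intersection(_halfplane(c, u, state.fronts[(i, j)], extent))
        if poly.is_empty:
            return poly
    for (u, h0, f) in state.walls.get(i, []):
        poly = poly.intersection(_halfplane(c, u, min(f, state.lam_cum * h0),
                                            extent))
    return poly


def _halfplane(c, u, support, extent):
    """{x : (x - c) · u <= support} as a large shapely box."""
    t = np.array([-u[1], u[0]])
    p = c + u * support
    big = 4 * extent
    return Polygon(
        [p + t * big, p - t * big, p - t * big - u * big, p + t * big - u * big]
    )


def tile_areas(state: GrowthState) -> np.ndarray:
    nm = state.neighbor_map()
    return np.array(
        [tile_polygon(state, i, nm[i]).area for i in range(state.n_tiles)]
    )


def coverage_fraction(state: GrowthState, region: Polygon) -> float:
    """Tiled area within ``region`` over the region area.

    Tiles are pairwise disjoint by construction, so the covered area is the
    sum of per-tile intersections.
    """
    if region.is_empty or region.area <= 0:
        raise ValueError("empty region")
    nm = state.neighbor_map()
    covered = sum(
        tile_polygon(state, i, nm[i]).intersection(region).area
        for i in range(state.n_tiles)
    )
    return min(1.0, covered / region.area)


def substrate_region(state: GrowthState) -> Polygon:
    if state.substrate0 is None:
        raise ValueError("state has no substrate outline")
    return _scale_polygon(state.substrate0, state.lam_cum)


def _scale_polygon(poly: Polygon, s: float) -> Polygon:
    xy = np.asarray(poly.exterior.coords) * s
    return Polygon(xy)


def propose_new_tiles(state: GrowthState, gap_area_threshold: float,
                      region: Polygon | None = None) -> list:
    """Uncovered connected regions exceeding the area threshold.

    Returns (centroid, area) candidates — the sites where a constant-rate
    scenario would have to insert new tiles.  Detection only: nothing is
    inserted.
    """
    if gap_area_threshold <= 0:
        raise ValueError("threshold must be positive")
    if region is None:
        region = substrate_region(state)
    nm = state.neighbor_map()
    tiles = unary_union(
        [tile_polygon(state, i, nm[i]) for i in range(state.n_tiles)]
    )
    uncovered = region.difference(tiles)
    geoms = getattr(uncovered, "geoms", [uncovered]) if not uncovered.is_empty else []
    out = []
    for g in geoms:
        if g.area > gap_area_threshold:
            out.append((np.array([g.centroid.x, g.centroid.y]), float(g.area)))
    return out


def voronoi_deviation(state: GrowthState) -> float:
    """Mean normalized offset of fiber boundaries from center midlines.

    Per fiber, the boundary (gap midline; contact point once g = 0) sits at
    f_ij + g/2 from centre i; its offset from the equidistant point d/2 is
    (f_ij − f_ji)/2.  Returns the mean of |offset| / d_ij over fibers: 0 for
    a Voronoi-symmetric state.
    """
    pairs = state.pairs()
    if not pairs:
        return 0.0
    dev = [
        abs(state.fronts[(i, j)] - state.fronts[(j, i)]) / (2 * state.distance(i, j))
        for (i, j) in pairs
    ]
    return float(np.mean(dev))


def run_cycles(
    state: GrowthState,
    lam_per_cycle: float,
    rule: tuple,
    n_cycles: int,
    region: Polygon | None = None,
) -> tuple:
    """Apply expand -> appose for ``n_cycles`` and record a trajectory.

    ``rule`` is ``("constant", delta)`` or ``("proportional", k)``.  The
    per-cycle record holds tile count (tiles with positive area), coverage
    over ``region`` (default: the expanding substrate outline), gap
    statistics and the Voronoi deviation; tile-area arrays are kept for
    rescaled-distribution comparisons.  Returns (final_state, trajectory).
    Deterministic: the dynamics contain no randomness beyond the initial
    state.
    """
    kind, param = rule
    if kind not in ("constant", "proportional"):
        raise ValueError(f"unknown rule {kind!r}")
    rows = []
    areas_per_cycle = []
    current = state
    for cycle in range(1, n_cycles + 1):
        current = expand_substrate(current, lam_per_cycle)
        if kind == "constant":
            current = appose_constant(current, param)
        else:
            current = appose_proportional(current, param)
        current.step = cycle
        areas = tile_areas(current)
        gaps = np.array([current.gap(i, j) for (i, j) in current.pairs()])
        reg = region if region is not None else (
            substrate_region(current) if current.substrate0 is not None else None
        )
        cov = coverage_fraction(current, reg) if reg is not None else float("nan")
        rows.append(
            {
                "cycle": cycle,
                "tile_count": int((areas > 0).sum()),
                "coverage": cov,
                "mean_gap": float(gaps.mean()) if len(gaps) else 0.0,
                "median_gap": float(np.median(gaps)) if len(gaps) else 0.0,
                "voronoi_deviation": voronoi_deviation(current),
                "substrate_scale": current.lam_cum,
            }
        )
        areas_per_cycle.append(areas)
    traj = GrowthTrajectory(table=pd.DataFrame(rows), areas=areas_per_cycle)
    return current, traj
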