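"""Tessellation-level statistics.

Polygon-class frequencies and Euler/topology identities; peak-rescaled
self-similar size distributions; and log-log regressions of distribution
peaks against substrate surface area, with isometric reference slopes from
dimensional analysis (length ~ area^0.5, area ~ area^1, volume ~ area^1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import Tessellation

__all__ = [
    "DistributionSummary",
    "RegressionResult",
    "polygon_frequency",
    "euler_characteristic",
    "hexagonal_deficiency",
    "peak_of_distribution",
    "rescale_distribution",
    "self_similarity_distance",
    "loglog_peak_regression",
    "neighbor_size_relation",
]

ISOMETRIC_SLOPES = {"width": 0.5, "thickness": 0.5, "plane_area": 1.0, "volume": 1.5}

# common rescaled-axis grid: x = value / mode
RESCALED_GRID = np.linspace(0.0, 4.0, 81)


@dataclass
class DistributionSummary:
    """A size distribution with its histogram, mode and rescaled density."""

    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float
    rescaled_x: np.ndarray      # bin centres of value/mode
    rescaled_density: np.ndarray  # normalized so the maximum is 1


@dataclass
class RegressionResult:
    """OLS fit of log10(peak) on log10(surface area)."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    isometric_slope: float
    n: int

    def summary(self) -> str:
        return (
            f"slope m' = {self.slope:.4f} (95% CI {self.ci_low:.4f}"
            f"–{self.ci_high:.4f}), isometric m = {self.isometric_slope}, "
            f"n = {self.n}"
        )


def polygon_frequency(classes: dict, interior_only: bool = False,
                      boundary_flags: dict | None = None) -> pd.DataFrame:
    """Count and fraction of tiles per polygon class n.

    ``classes`` maps tile id -> neighbour count; tiles flagged True in
    ``boundary_flags`` are excluded when ``interior_only`` (their degree
    undercounts their sides).
    """
    if not classes:
        raise ValueError("empty class map")
    items = classes.items()
    if interior_only and boundary_flags:
        items = [(k, v) for k, v in items if not boundary_flags.get(k, False)]
        if not items:
            raise ValueError("no interior tiles")
    ns = np.array([v for _, v in items])
    uniq, counts = np.unique(ns, return_counts=True)
    return pd.DataFrame(
        {"n": uniq, "count": counts, "fraction": counts / counts.sum()}
    ).set_index("n")


def _dedup_edges(tess: Tessellation):
    edges = set()
    for ring in tess.faces:
        for k in range(len(ring)):
            edges.add(tuple(sorted((ring[k], ring[(k + 1) % len(ring)]))))
    return edges


def euler_characteristic(tess: Tessellation) -> int:
    """V − E + F of a closed tessellation (2 for sphere-like, 0 for torus)."""
    if not tess.closed:
        raise ValueError(
            "Euler characteristic requires a closed tessellation; open "
            "surfaces need boundary-aware accounting (real shells are almost, "
            "but not fully, covered — treat boundary cells separately)"
        )
    used = sorted({v for ring in tess.faces for v in ring})
    V = len(used)
    E = len(_dedup_edges(tess))
    F = len(tess.faces)
    return V - E + F


def _vertex_valences(tess: Tessellation) -> dict:
    val: dict = {}
    for ring in tess.faces:
        for k in range(len(ring)):
            e = tuple(sorted((ring[k], ring[(k + 1) % len(ring)])))
            val[e] = val.get(e, 0) + 1
    degree: dict = {}
    for (a, b) in val:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    return degree


def hexagonal_deficiency(tess: Tessellation) -> int:
    """Σ over faces of (6 − n): the pentagon/heptagon bookkeeping sum.

    For a trivalent closed tessellation this equals 6·χ — hence 12 on a
    sphere — and reduces to (#pentagons − #heptagons) when only 5/6/7-gons
    occur.  Non-trivalent vertices violate the identity and raise.
    """
    if not tess.closed:
        raise ValueError("hexagonal deficiency requires a closed tessellation")
    for vtx, deg in _vertex_valences(tess).items():
        if deg != 3:
            raise ValueError(f"vertex {vtx} has valence {deg}; not trivalent")
    return int(sum(6 - len(ring) for ring in tess.faces))


def _fd_bin_edges(values: np.ndarray) -> np.ndarray:
    """Freedman–Diaconis bin edges (falls back to sqrt rule if IQR = 0)."""
    values = np.sort(values)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr > 0:
        width = 2 * iqr / len(values) ** (1 / 3)
        nbins = max(1, int(np.ceil((values[-1] - values[0]) / width)))
    else:
        nbins = max(1, int(np.sqrt(len(values))))
    return np.linspace(values[0], values[-1], nbins + 1)


def peak_of_distribution(values, bin_edges=None, smooth: int = 2) -> float:
    """Histogram mode with parabolic refinement over the modal bin.

    The "peak value" of a morphometric distribution: Freedman–Diaconis
    binning by default (pass explicit ``bin_edges`` for a fixed rule), a
    moving average of half-width ``smooth`` bins to damp count noise, then
    a parabola through the modal bin and its two neighbours refines the
    location sub-bin.  Deterministic for a fixed bin rule.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need >= 10 values for a peak estimate")
    if np.allclose(values, values[0]):
        return float(values[0])
    if bin_edges is None:
        bin_edges = _fd_bin_edges(values)
    counts, edges = np.histogram(values, bins=bin_edges)
    counts = counts.astype(float)
    if smooth > 0 and len(counts) > 2 * smooth + 1:
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        counts = np.convolve(counts, kernel, mode="same")
    i = int(np.argmax(counts))
    centres = (edges[:-1] + edges[1:]) / 2
    if 0 < i < len(counts) - 1:
        y0, y1, y2 = counts[i - 1], counts[i], counts[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            return float(centres[i] + shift * (edges[1] - edges[0]))
    return float(centres[i])


def rescale_distribution(values, mode: float | None = None) -> DistributionSummary:
    """Rescale a distribution so its peak sits at 1.

    Divides values by the mode and bins them on the shared rescaled grid;
    the density is normalized to a maximum of 1 (the convention that makes
    self-similar distributions overlap).
    """
    values = np.asarray(values, dtype=float)
    if mode is None:
        mode = peak_of_distribution(values)
    if mode <= 0:
        raise ValueError("mode must be positive")
    edges = _fd_bin_edges(values)
    counts, edges = np.histogram(values, bins=edges)
    x = values / mode
    r_counts, _ = np.histogram(x, bins=RESCALED_GRID)
    dens = r_counts.astype(float)
    if dens.max() > 0:
        dens = dens / dens.max()
    centres = (RESCALED_GRID[:-1] + RESCALED_GRID[1:]) / 2
    return DistributionSummary(
        values=values,
        bin_edges=edges,
        counts=counts,
        mode=float(mode),
        rescaled_x=centres,
        rescaled_density=dens,
    )


def self_similarity_distance(a: DistributionSummary, b: DistributionSummary) -> float:
    """L1 distance in [0, 2] between two rescaled densities.

    Both densities are renormalized to unit area on the common rescaled
    grid, so identical shapes give 0 and disjoint supports give 2.
    """
    if len(a.rescaled_x) != len(b.rescaled_x) or not np.allclose(
        a.rescaled_x, b.rescaled_x
    ):
        raise ValueError("distributions are not on a common rescaled grid")
    dx = np.diff(RESCALED_GRID)
    pa, pb = a.rescaled_density.copy(), b.rescaled_density.copy()
    for p in (pa, pb):
        area = (p * dx).sum()
        if area <= 0:
            raise ValueError("empty density")
    pa /= (pa * dx).sum()
    pb /= (pb * dx).sum()
    return float((np.abs(pa - pb) * dx).sum())


def loglog_peak_regression(
    surface_areas, peaks, isometric_exponent: float, rma: bool = False
) -> RegressionResult:
    """OLS of log10(peak) on log10(surface area) with an isometric reference.

    ``isometric_exponent`` is the slope isometry predicts for the measured
    quantity (0.5 for lengths, 1 for areas, 1.5 for volumes against surface
    area).  ``rma=True`` switches to reduced major axis (geometric-mean)
    regression; OLS is the default.
    """
    sa = np.asarray(surface_areas, dtype=float)
    pk = np.asarray(peaks, dtype=float)
    if len(sa) < 3:
        raise ValueError("need >= 3 specimens")
    if np.any(sa <= 0) or np.any(pk <= 0):
        raise ValueError("inputs must be positive for log-log regression")
    x, y = np.log10(sa), np.log10(pk)
    res = sps.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    if rma:
        sign = np.sign(slope) if slope != 0 else 1.0
        slope = sign * np.std(y, ddof=1) / np.std(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
    n = len(x)
    if res.stderr > 0 and n > 2:
        tcrit = sps.t.ppf(0.975, n - 2)
        lo, hi = slope - tcrit * res.stderr, slope + tcrit * res.stderr
    else:
        lo = hi = slope
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(lo),
        ci_high=float(hi),
        isometric_slope=float(isometric_exponent),
        n=n,
    )


def neighbor_size_relation(records: pd.DataFrame) -> tuple:
    """Mean plane area per polygon class, plus a rank correlation.

    Tiles with more neighbours should be larger (they arose from growth
    centres with more room) — a Lewis-law-like relation.  Returns a table of
    class means and the Spearman correlation of n vs. area across tiles.
    """
    df = records.dropna(subset=["plane_area_um2"])
    if df["n_neighbors"].nunique() < 2:
        raise ValueError("need >= 2 distinct neighbour-count classes")
    table = (
        df.groupby("n_neighbors")["plane_area_um2"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_area_um2"})
    )
    if df["plane_area_um2"].nunique() == 1:
        rho = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(
                sps.spearmanr(df["n_neighbors"], df["plane_area_um2"]).statistic
            )
    return table, rho
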