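"""End-to-end conveniences: the default study phantom, the full
segmentation chain, and truth-comparison helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import segmentation as seg
from .rag import build_rag
from .synthetic import (
    Phantom,
    SurfaceSpec,
    sample_hardcore_points,
    voronoi_tessellation,
    voxelize_shell,
)
from .volumes import GrayscaleVolume, LabelVolume

__all__ = [
    "default_phantom",
    "segment_volume",
    "match_labels",
    "adjacency_f1",
]

#: Default study conditions for the slab-shell phantom: a 1.5 x 1.5 mm flat
#: shell, 100 µm thick, voxelized at 5 µm, with 400 hard-core growth centres
#: at >= 50 µm spacing, 10 µm intertesseral gaps, two ~7.5 µm-radius lacunae
#: per tile, half-voxel blur and additive noise at 10% of the contrast.
DEFAULT_PHANTOM = dict(
    extent=(1500.0, 1500.0),
    shell_thickness=100.0,
    voxel=5.0,
    n_seeds=400,
    min_spacing=50.0,
    gap_width=10.0,
    lacunae=(2, 7.5),
    noise_sd=0.1,
    blur_sigma=2.5,
    seed=7,
)


def default_phantom(**overrides) -> Phantom:
    """Generate the default slab-shell phantom (see ``DEFAULT_PHANTOM``)."""
    p = {**DEFAULT_PHANTOM, **overrides}
    surface = SurfaceSpec("slab-shell", extent=p["extent"])
    points = sample_hardcore_points(
        surface, p["n_seeds"], p["min_spacing"], seed=p["seed"]
    )
    tess = voronoi_tessellation(points, surface)
    return voxelize_shell(
        tess,
        shell_thickness=p["shell_thickness"],
        gap_width=p["gap_width"],
        voxel=p["voxel"],
        lacunae=p["lacunae"],
        noise_sd=p["noise_sd"],
        blur_sigma=p["blur_sigma"],
        seed=p["seed"],
    )


def segment_volume(
    gray: GrayscaleVolume,
    threshold: float = 0.5,
    min_component: int = 100,
    max_void_extent: int = 1000,
    persistence: float = 20.0,
    connectivity: int = 26,
    min_volume: float = 0.0,
    min_thickness: float = 0.0,
) -> LabelVolume:
    """Threshold -> clean -> EDT -> hierarchical watershed -> size filter.

    The default persistence (µm) is of the order of half the expected tile
    half-width; it is the knob that decides which watershed basins are
    distinct tiles.
    """
    binary = seg.threshold_volume(gray, threshold)
    binary = seg.clean_binary(
        binary, min_component=min_component, fill_enclosed_voids=True,
        max_void_extent=max_void_extent,
    )
    dist = seg.distance_map(binary)
    labels = seg.watershed_instances(dist, persistence=persistence,
                                     connectivity=connectivity)
    if min_volume > 0 or min_thickness > 0:
        labels = seg.remove_partial_tesserae(labels, min_volume, min_thickness)
    return labels


def match_labels(pred: LabelVolume, truth: LabelVolume) -> pd.DataFrame:
    """Best-overlap matching between predicted and truth labels.

    Returns one row per predicted label with its majority truth label, the
    overlap voxel count, and both volumes (voxels) — the basis for
    per-tile parameter-recovery checks.
    """
    p = pred.data.ravel()
    t = truth.data.ravel()
    both = (p > 0) & (t > 0)
    pairs = np.column_stack([p[both], t[both]])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    df = pd.DataFrame({"pred": uniq[:, 0], "truth": uniq[:, 1], "overlap": counts})
    best = df.sort_values("overlap", ascending=False).drop_duplicates("pred")
    pred_counts = np.bincount(p)
    truth_counts = np.bincount(t)
    best = best.assign(
        pred_voxels=pred_counts[best["pred"]],
        truth_voxels=truth_counts[best["truth"]],
    )
    return best.sort_values("pred").reset_index(drop=True)


def adjacency_f1(pred_edges: set, truth_edges: set) -> float:
    """F1 score of a predicted edge set against the truth adjacency."""
    pred_edges = {tuple(sorted(e)) for e in pred_edges}
    truth_edges = {tuple(sorted(e)) for e in truth_edges}
    tp = len(pred_edges & truth_edges)
    if tp == 0:
        return 0.0
    precision = tp / len(pred_edges)
    recall = tp / len(truth_edges)
    return 2 * precision * recall / (precision + recall)


def rag_against_truth(phantom: Phantom, labels: LabelVolume,
                      min_contact: int = 1, bridge_gap: float = 0.0) -> float:
    """Build a RAG from segmented labels and score it against the phantom's
    truth adjacency (edges mapped through best-overlap label matching)."""
    graph = build_rag(labels, min_contact=min_contact, bridge_gap=bridge_gap)
    matching = match_labels(labels, phantom.truth_labels)
    to_truth = dict(zip(matching["pred"], matching["truth"]))
    pred_edges = set()
    for a, b in graph.edges():
        ta, tb = to_truth.get(a), to_truth.get(b)
        if ta is None or tb is None or ta == tb:
            continue
        pred_edges.add((min(ta, tb), max(ta, tb)))
    return adjacency_f1(pred_edges, phantom.truth_adjacency)
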