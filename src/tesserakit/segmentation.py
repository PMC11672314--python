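"""Instance segmentation of tessellated shell volumes.

The pipeline mirrors established tessellated-tissue workflows: grayscale
threshold -> binary clean-up (small components, enclosed lacunar voids) ->
Euclidean distance transform -> hierarchical watershed with persistence-based
merging of shallow maxima -> scriptable proofreading edits.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from .volumes import BinaryVolume, DistanceVolume, GrayscaleVolume, LabelVolume

__all__ = [
    "threshold_volume",
    "suggest_threshold",
    "clean_binary",
    "distance_map",
    "signed_distance_map",
    "watershed_instances",
    "edit_labels",
    "remove_partial_tesserae",
]

# foreground 26-connectivity with complementary 6-connected background:
# the standard pairing for 3-D binary topology
_FG_STRUCT = np.ones((3, 3, 3), dtype=bool)
_BG_STRUCT = ndimage.generate_binary_structure(3, 1)


def threshold_volume(gray: GrayscaleVolume, level: float) -> BinaryVolume:
    """Binary foreground = voxels with intensity >= ``level``.

    The level is a plain config choice, never inferred silently; see
    :func:`suggest_threshold` for an automatic Otsu proposal.
    """
    return BinaryVolume(gray.data >= level, gray.voxel_size)


def suggest_threshold(gray: GrayscaleVolume) -> float:
    """Otsu threshold proposal for two-phase volumes (advisory only)."""
    return float(threshold_otsu(gray.data))


def clean_binary(
    bin_vol: BinaryVolume,
    min_component: int = 0,
    fill_enclosed_voids: bool = True,
    max_void_extent: int = 10**9,
) -> BinaryVolume:
    """Remove small foreground specks and fill enclosed lacunar voids.

    Foreground components (26-connected) smaller than ``min_component``
    voxels are deleted.  Background components (6-connected) that do not
    reach the volume border — i.e. are fully enclosed by foreground — and are
    at most ``max_void_extent`` voxels are filled.  Idempotent.
    """
    if min_component < 0 or max_void_extent < 0:
        raise ValueError("parameters must be >= 0")
    fg = bin_vol.data.copy()
    if min_component > 0 and fg.any():
        lab, n = ndimage.label(fg, structure=_FG_STRUCT)
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts[1:] < min_component) + 1
        if len(small):
            fg[np.isin(lab, small)] = False
    if fill_enclosed_voids and (~fg).any():
        bg_lab, n = ndimage.label(~fg, structure=_BG_STRUCT)
        border = np.unique(
            np.concatenate(
                [
                    bg_lab[0].ravel(), bg_lab[-1].ravel(),
                    bg_lab[:, 0].ravel(), bg_lab[:, -1].ravel(),
                    bg_lab[:, :, 0].ravel(), bg_lab[:, :, -1].ravel(),
                ]
            )
        )
        counts = np.bincount(bg_lab.ravel())
        enclosed = np.ones(n + 1, dtype=bool)
        enclosed[0] = False
        enclosed[border[border > 0]] = False
        enclosed &= counts <= max_void_extent
        if enclosed.any():
            fg[enclosed[bg_lab]] = True
    return BinaryVolume(fg, bin_vol.voxel_size)


def distance_map(bin_vol: BinaryVolume) -> DistanceVolume:
    """Unsigned Euclidean distance (µm) from foreground to background."""
    fg = bin_vol.data
    if not fg.any():
        raise ValueError("empty foreground")
    if fg.all():
        raise ValueError("all-foreground volume has no background reference")
    d = ndimage.distance_transform_edt(fg, sampling=bin_vol.voxel_size)
    return DistanceVolume(d, bin_vol.voxel_size, signed=False)


def signed_distance_map(bin_vol: BinaryVolume) -> DistanceVolume:
    """Signed distance to the tissue-background interface.

    Negative inside the mineralized foreground, positive outside; zero
    crossing within one voxel of the interface.
    """
    fg = bin_vol.data
    if not fg.any() or fg.all():
        raise ValueError("need both foreground and background")
    v = bin_vol.voxel_size
    inside = ndimage.distance_transform_edt(fg, sampling=v)
    outside = ndimage.distance_transform_edt(~fg, sampling=v)
    return DistanceVolume(outside - inside, v, signed=True)


def watershed_instances(
    dist: DistanceVolume,
    persistence: float = 0.0,
    connectivity: int = 26,
) -> LabelVolume:
    """Hierarchical watershed on a distance map with persistence merging.

    Labels grow from the regional maxima of the distance map.  Before
    growing, maxima whose dynamic (peak height minus separating saddle) is
    below ``persistence`` (µm) are merged into their taller neighbour via the
    h-maxima transform (grayscale reconstruction of ``dist - persistence``
    under ``dist``).  Background (zero distance) stays label 0.
    """
    if dist.signed:
        raise ValueError("watershed_instances expects an unsigned distance map")
    if persistence < 0:
        raise ValueError("persistence must be >= 0")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    conn_rank = {6: 1, 18: 2, 26: 3}[connectivity]
    struct = ndimage.generate_binary_structure(3, conn_rank)
    d = dist.data
    fg = d > 0
    if persistence > 0:
        recon = reconstruction(np.where(fg, d - persistence, 0.0), d,
                               method="dilation", footprint=struct)
    else:
        recon = d
    # regional maxima of the reconstructed map are the surviving markers
    # (local_maxima handles plateaus, which EDT ties produce routinely)
    maxima = fg & local_maxima(recon, footprint=struct).astype(bool)
    markers, _ = ndimage.label(maxima, structure=struct)
    # a component's global maximum always survives (infinite dynamic): give
    # any marker-less foreground component one marker at its own maximum
    comp, n_comp = ndimage.label(fg, structure=struct)
    if n_comp:
        has_marker = np.zeros(n_comp + 1, dtype=bool)
        has_marker[np.unique(comp[markers > 0])] = True
        missing = [c for c in range(1, n_comp + 1) if not has_marker[c]]
        if missing:
            next_id = int(markers.max())
            argmaxes = ndimage.maximum_position(d, comp, missing)
            for pos in argmaxes:
                next_id += 1
                markers[tuple(pos)] = next_id
    labels = watershed(-d, markers=markers, mask=fg, connectivity=struct)
    return LabelVolume(labels.astype(np.int32), dist.voxel_size)


def edit_labels(labels: LabelVolume, edits: list) -> LabelVolume:
    """Apply scriptable proofreading edits in order.

    ``edits`` entries are ``("merge", a, b)`` — relabel b into a — or
    ``("split", id, seed_points)`` where seed points are voxel-index triples
    inside the id's support; the split re-runs a marker-based watershed on
    the region's own distance transform.  Every edit is appended to the log.
    """
    out = labels.copy()
    data = out.data
    for edit in edits:
        op = edit[0]
        if op == "merge":
            _, a, b = edit
            for lab_id in (a, b):
                if not (data == lab_id).any():
                    raise ValueError(f"unknown label id {lab_id}")
            data[data == b] = a
            out.log.append(("merge", int(a), int(b)))
        elif op == "split":
            _, lab_id, seeds = edit
            support = data == lab_id
            if not support.any():
                raise ValueError(f"unknown label id {lab_id}")
            for s in seeds:
                if not support[tuple(s)]:
                    raise ValueError(f"split seed {tuple(s)} outside label {lab_id}")
            d = ndimage.distance_transform_edt(support)
            markers = np.zeros_like(data)
            next_id = int(data.max())
            new_ids = [lab_id] + [next_id + k for k in range(1, len(seeds))]
            for nid, s in zip(new_ids, seeds):
                markers[tuple(s)] = nid
            pieces = watershed(-d, markers=markers, mask=support)
            data[support] = pieces[support]
            out.log.append(("split", int(lab_id), [tuple(map(int, s)) for s in seeds]))
        else:
            raise ValueError(f"unknown edit {op!r}")
    return out


def remove_partial_tesserae(
    labels: LabelVolume, min_volume: float = 0.0, min_thickness: float = 0.0
) -> LabelVolume:
    """Drop thin, partially formed tiles below volume/thickness thresholds.

    ``min_volume`` is in µm³; ``min_thickness`` (µm) is compared against the
    smallest axis-aligned bounding-box side of the label (thin-shell tiles
    are thinnest along their outward axis).  Removed ids are logged.
    """
    if min_volume < 0 or min_thickness < 0:
        raise ValueError("thresholds must be >= 0")
    out = labels.copy()
    data = out.data
    v = out.voxel_size
    counts = np.bincount(data.ravel())
    removed = []
    objects = ndimage.find_objects(data)
    for lab_id in out.ids():
        sl = objects[lab_id - 1]
        vol = counts[lab_id] * v**3
        thick = min((s.stop - s.start) for s in sl) * v
        if vol < min_volume or thick < min_thickness:
            removed.append(int(lab_id))
    if removed:
        data[np.isin(data, removed)] = 0
    out.log.append(("remove_partial", removed))
    return out
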