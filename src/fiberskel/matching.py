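"""Plane-scanning template matcher: simultaneous binarization and
skeletonization.

A 2D search plane moves through the stack along each scan axis.  Every
centered s x s search section is mean-subtracted, unit-normalized, and
compared to the template by Euclidean distance D (in [0, 2] for unit
vectors).  Pixels whose mismatch exceeds the threshold become fluid; the
remaining pixels form localized clusters (fiber cross-sections), reduced to
their local mismatch minima -- the medial axis.  The per-axis binary stacks
are OR-combined into the final reconstruction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import AXES, BinaryStack, ImageStack, MismatchField, Template

__all__ = [
    "mismatch_plane",
    "mismatch_volume",
    "skeleton_plane",
    "scan_axis",
    "combine_scans",
    "global_threshold_binarize",
]

#: Mismatch assigned to border-margin pixels and to all-constant windows
#: (whose mean-subtracted vector is zero and cannot be normalized).  2 is the
#: largest possible distance between unit vectors, so such pixels can never be
#: classified solid for any threshold in (0, 2).
MAX_MISMATCH = 2.0


def _mismatch_values(plane: np.ndarray, template: Template) -> np.ndarray:
    """Mismatch distances for one search plane (vectorized).

    For unit vectors t and w, D^2 = 2 - 2 * <w, t>, with
    <w, t> = (W.t - mu * sum(t)) / ||W - mu||, so three small correlations
    (W.t, sum W, sum W^2) give the whole field.
    """
    plane = np.asarray(plane, dtype=np.float64)
    s = template.size
    if plane.shape[0] < s or plane.shape[1] < s:
        raise ValueError(
            f"search plane {plane.shape} smaller than template size {s}"
        )
    mu = template.global_mean
    t = template.pattern
    ones = np.ones_like(t)
    num = ndimage.correlate(plane, t, mode="constant")
    win_sum = ndimage.correlate(plane, ones, mode="constant")
    win_sq = ndimage.correlate(plane**2, ones, mode="constant")
    norm_sq = win_sq - 2.0 * mu * win_sum + s * s * mu * mu
    norm = np.sqrt(np.maximum(norm_sq, 0.0))
    cos = np.zeros_like(plane)
    ok = norm > 1e-12
    cos[ok] = (num[ok] - mu * t.sum()) / norm[ok]
    np.clip(cos, -1.0, 1.0, out=cos)
    d = np.sqrt(np.maximum(2.0 - 2.0 * cos, 0.0))
    d[~ok] = MAX_MISMATCH
    half = s // 2
    d[:half, :] = MAX_MISMATCH
    d[-half:, :] = MAX_MISMATCH
    d[:, :half] = MAX_MISMATCH
    d[:, -half:] = MAX_MISMATCH
    return d


def mismatch_plane(plane: np.ndarray, template: Template,
                   plane_index: int = 0) -> MismatchField:
    """Score the mismatch of every interior pixel of a search plane against
    the template.  Border-margin pixels carry the maximal mismatch 2."""
    return MismatchField(values=_mismatch_values(plane, template),
                         plane_index=plane_index)


def mismatch_volume(stack: ImageStack, template: Template) -> np.ndarray:
    """Mismatch fields for every plane perpendicular to the template's scan
    axis, stacked into a float32 volume indexed like the input stack."""
    axis = AXES[template.scan_axis]
    planes = np.moveaxis(np.asarray(stack.voxels, dtype=np.float64), axis, 0)
    out = np.empty(planes.shape, dtype=np.float32)
    for i in range(planes.shape[0]):
        out[i] = _mismatch_values(planes[i], template)
    return np.moveaxis(out, 0, axis)


def skeleton_plane(field: MismatchField | np.ndarray, threshold: float) -> np.ndarray:
    """Reduce a mismatch field to medial-axis pixels.

    Pixels with D >= threshold are fluid; within the remaining clusters, the
    local minima of D are kept: a pixel survives iff none of its 4 edge
    neighbors inside the cluster mask has a smaller D (ties broken by
    row-major order, keeping one pixel per tied plateau).  Elongated fiber
    cross-sections thus reduce to their medial ridge; merging clusters retain
    one representative per mismatch basin; diagonal near-duplicates may
    coexist, which is what lets the reconstruction thicken gradually as the
    threshold grows.  No two surviving pixels are ever 4-adjacent.
    """
    values = field.values if isinstance(field, MismatchField) else np.asarray(field)
    if not 0.0 < threshold < 2.0:
        raise ValueError("threshold must lie in (0, 2)")
    mask = values < threshold
    if not mask.any():
        return np.zeros(values.shape, dtype=bool)
    # Pixels outside the cluster mask never suppress a candidate.
    eff = np.where(mask, values, np.inf)
    pad = np.pad(eff, 1, constant_values=np.inf)
    keep = mask.copy()
    h, w = values.shape
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = pad[1 + di : 1 + di + h, 1 + dj : 1 + dj + w]
        later = di > 0 or (di == 0 and dj > 0)  # neighbor after p row-major
        if later:
            keep &= eff <= nb
        else:
            keep &= eff < nb
    return keep


def scan_axis(
    stack: ImageStack,
    template: Template,
    threshold: float,
    precomputed_mismatch: np.ndarray | None = None,
) -> BinaryStack:
    """Run one full plane scan along the template's axis and assemble the
    per-plane skeletons into a binary stack.  The border margin (s//2 voxels)
    is fluid phase by construction."""
    axis = AXES[template.scan_axis]
    for sec_axis in (a for a in range(3) if a != axis):
        if stack.shape[sec_axis] < template.size:
            raise ValueError(
                f"stack extent {stack.shape[sec_axis]} along section axis "
                f"{sec_axis} is smaller than template size {template.size}"
            )
    if precomputed_mismatch is None:
        precomputed_mismatch = mismatch_volume(stack, template)
    fields = np.moveaxis(precomputed_mismatch, axis, 0)
    out = np.empty(fields.shape, dtype=bool)
    for i in range(fields.shape[0]):
        out[i] = skeleton_plane(fields[i], threshold)
    return BinaryStack(voxels=np.moveaxis(out, 0, axis),
                       voxel_size=stack.voxel_size)


def combine_scans(stacks: list[BinaryStack]) -> BinaryStack:
    """Voxelwise logical OR of per-axis scan results."""
    if not stacks:
        raise ValueError("no scans to combine")
    shape = stacks[0].shape
    for s in stacks[1:]:
        if s.shape != shape:
            raise ValueError(f"shape mismatch: {s.shape} vs {shape}")
    out = np.zeros(shape, dtype=bool)
    for s in stacks:
        out |= s.voxels
    return BinaryStack(voxels=out, voxel_size=stacks[0].voxel_size)


def global_threshold_binarize(stack: ImageStack,
                              intensity_threshold: float) -> BinaryStack:
    """Baseline binarizer: solid iff B >= threshold.  No skeletonization.

    Kept for comparison: on realistic stacks the solid- and fluid-phase
    brightness histograms overlap, so no single threshold reconstructs the
    network without both false positives and false negatives.
    """
    if not 0 <= intensity_threshold <= 255:
        raise ValueError("intensity threshold must lie in [0, 255]")
    return BinaryStack(voxels=np.asarray(stack.voxels) >= intensity_threshold,
                       voxel_size=stack.voxel_size)
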