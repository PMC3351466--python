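"""Topology-driven mismatching-threshold optimization.

Voxelized random line networks share a universal property: the most probable
number of solid 26-neighbors of a solid voxel is 3, almost independently of
network density.  The mismatching threshold is therefore tuned until the
OR-combined reconstruction reproduces this signature: a threshold that is too
low fragments the fibers (mode < 3), one that is too high thickens them
(mode > 3).  No user input is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import BinaryStack, ImageStack, NeighborCountDistribution, Template
from .matching import combine_scans, mismatch_volume, scan_axis

__all__ = [
    "neighbor_count_distribution",
    "optimize_threshold",
    "ThresholdSearchError",
    "TARGET_NEIGHBOR_MODE",
]

logger = logging.getLogger(__name__)

#: Target mode of the neighbor-count distribution.  3 is the universal value
#: for line networks; other porous topologies would need a different target
#: (which requires a-priori knowledge of the structure), so this is a module
#: constant rather than a user parameter.
TARGET_NEIGHBOR_MODE = 3

#: Stop refining threshold edges once the bracketing interval is narrower
#: than this (threshold units on the (0, 2) mismatch scale).
EDGE_TOLERANCE = 0.01

_K26 = np.ones((3, 3, 3), dtype=np.int64)
_K26[1, 1, 1] = 0


class ThresholdSearchError(RuntimeError):
    """No threshold reproduces the line-network topology signature."""


def neighbor_count_distribution(binary: BinaryStack) -> NeighborCountDistribution:
    """Histogram of the number of solid voxels among the 26 neighbors of each
    solid voxel (out-of-volume neighbors count as fluid)."""
    vol = binary.voxels
    if not vol.any():
        return NeighborCountDistribution(counts=np.zeros(27, dtype=np.int64))
    neighbors = ndimage.convolve(vol.astype(np.int64), _K26, mode="constant")
    counts = np.bincount(neighbors[vol], minlength=27)
    return NeighborCountDistribution(counts=counts[:27])


@dataclass
class _Evaluation:
    threshold: float
    mode: int
    n_solid: int


class _Pipeline:
    """Caches per-axis mismatch volumes so that re-skeletonizing at a new
    threshold costs only the cheap cluster-reduction step."""

    def __init__(self, stack: ImageStack, templates: list[Template]):
        self.stack = stack
        self.templates = templates
        self.volumes = [mismatch_volume(stack, t) for t in templates]

    def reconstruct(self, threshold: float) -> BinaryStack:
        scans = [
            scan_axis(self.stack, t, threshold, precomputed_mismatch=v)
            for t, v in zip(self.templates, self.volumes)
        ]
        return combine_scans(scans)

    def evaluate(self, threshold: float) -> _Evaluation:
        recon = self.reconstruct(threshold)
        dist = neighbor_count_distribution(recon)
        ev = _Evaluation(threshold=threshold, mode=dist.mode,
                         n_solid=dist.n_solid)
        logger.debug("threshold=%.4f mode=%d n_solid=%d",
                     ev.threshold, ev.mode, ev.n_solid)
        return ev


def _bisect_edge(evaluate, lo: float, hi: float, predicate) -> float:
    """Edge between predicate=False at lo and predicate=True at hi."""
    while hi - lo > EDGE_TOLERANCE:
        mid = 0.5 * (lo + hi)
        if predicate(evaluate(mid)):
            hi = mid
        else:
            lo = mid
    return hi


def optimize_threshold(
    stack: ImageStack,
    templates: list[Template],
    target_mode: int = TARGET_NEIGHBOR_MODE,
    coarse_step: float = 0.1,
    return_pipeline: bool = False,
):
    """Find the mismatching threshold whose reconstruction has neighbor-count
    mode equal to ``target_mode`` (3 for line networks).

    The search first walks a coarse threshold grid upward until the mode
    passes the target, then refines both edges of the target-mode interval by
    bisection (tolerance 0.01) and returns the interval midpoint.  The walk
    relies on the mode being non-decreasing with threshold in the operating
    regime; if the coarse walk finds no target-mode interval, a fine grid
    search over (0, 2) is used as a fallback before giving up.

    Raises
    ------
    ThresholdSearchError
        If no threshold in (0, 2) achieves the target mode -- the input does
        not look like an imaged line network.
    """
    pipe = _Pipeline(stack, templates)
    evals: dict[float, _Evaluation] = {}

    def ev(t: float) -> _Evaluation:
        t = round(t, 6)
        if t not in evals:
            evals[t] = pipe.evaluate(t)
        return evals[t]

    # Coarse upward walk through the operating regime, where the mode is
    # non-decreasing with threshold.  Beyond it, background noise floods the
    # search planes, the per-plane minima scatter, and the mode briefly
    # *drops* before climbing again as the flood densifies -- any mode-3
    # found past that collapse is spurious, so the walk stops there.
    grid = np.arange(coarse_step / 2, 2.0, coarse_step)
    first_true = last_true = None
    prev = None
    overshoot = None  # (lo, hi) bracketing a jump straight past the target
    collapse_t = None
    for t in grid:
        e = ev(t)
        if prev is not None and prev.mode >= 2 and e.mode < prev.mode:
            collapse_t = t
            logger.debug("mode collapse at threshold %.3f (%d -> %d): "
                         "leaving the operating regime",
                         t, prev.mode, e.mode)
            break
        if e.mode == target_mode:
            if first_true is None:
                first_true = t
            last_true = t
        elif e.mode > target_mode:
            if first_true is None:
                overshoot = (prev.threshold if prev is not None else 0.0, t)
            break
        prev = e

    if first_true is not None:
        lo_edge = first_true if first_true == grid[0] else _bisect_edge(
            ev, first_true - coarse_step, first_true,
            lambda e: e.mode >= target_mode,
        )
        hi_cap = collapse_t if collapse_t is not None else min(
            last_true + coarse_step, 2.0 - 1e-6
        )
        hi_edge = _bisect_edge(
            ev, last_true, hi_cap,
            lambda e: e.mode != target_mode,
        )
    elif overshoot is not None:
        # The mode jumped from below to above the target between two coarse
        # points; the target interval, if any, is a narrow sliver in between.
        lo_edge = _bisect_edge(
            ev, overshoot[0], overshoot[1],
            lambda e: e.mode >= target_mode,
        )
        hi_edge = _bisect_edge(
            ev, overshoot[0], overshoot[1],
            lambda e: e.mode > target_mode,
        )
        if hi_edge <= lo_edge or ev(
            0.5 * (lo_edge + hi_edge)
        ).mode != target_mode:
            t_star = _fail(ev, target_mode)
            return (t_star, pipe) if return_pipeline else t_star
    else:
        t_star = _fail(ev, target_mode, collapse_t)
        return (t_star, pipe) if return_pipeline else t_star

    t_star = 0.5 * (lo_edge + hi_edge)
    if ev(t_star).mode != target_mode:
        t_star = _fail(ev, target_mode, collapse_t)
        return (t_star, pipe) if return_pipeline else t_star
    logger.info("optimized threshold %.4f (interval [%.4f, %.4f])",
                t_star, lo_edge, hi_edge)
    return (t_star, pipe) if return_pipeline else t_star


def _fail(ev, target_mode, collapse_t=None, step: float = 0.05):
    """Fine grid sweep of the pre-collapse regime before giving up."""
    hi = collapse_t if collapse_t is not None else 2.0
    ts = [round(t, 6) for t in np.arange(step, hi, step)]
    results = [ev(t) for t in ts]
    # Re-detect the collapse on the fine grid.
    usable = []
    prev = None
    for e in results:
        if prev is not None and prev.mode >= 2 and e.mode < prev.mode:
            break
        usable.append(e)
        prev = e
    good = [e.threshold for e in usable if e.mode == target_mode]
    if good:
        t_star = float(0.5 * (min(good) + max(good)))
        if ev(t_star).mode != target_mode:
            t_star = float(np.median(good))
        return t_star
    achieved = sorted({e.mode for e in usable})
    raise ThresholdSearchError(
        "no threshold in (0, 2) yields neighbor-count mode "
        f"{target_mode}; achievable modes in the operating regime: "
        f"{achieved}. The input does not appear to contain a line-like "
        "fiber network."
    )
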