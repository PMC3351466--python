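"""Evaluation statistics for reconstructed fiber networks.

The central quantity is the nearest-obstacle-distance distribution p(d): the
distance from a uniform random test point to the closest solid voxel is a
proxy for the pore size of the network, and the Pearson correlation between
the p(d) of a ground-truth network and of its reconstruction measures
reconstruction fidelity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .datatypes import (
    BinaryStack,
    DistanceDistribution,
    ImageStack,
    LineNetwork,
)

__all__ = [
    "nearest_obstacle_distances",
    "nearest_obstacle_distribution",
    "distribution_correlation",
    "segment_angle_distributions",
    "intensity_histogram",
    "shared_bin_edges",
]

DEFAULT_N_POINTS = 100_000


def nearest_obstacle_distances(
    binary: BinaryStack,
    n_points: int = DEFAULT_N_POINTS,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Exact distances from uniform random test points to the nearest solid
    voxel center, in physical units (anisotropic voxels supported)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    solid = np.argwhere(binary.voxels)
    if len(solid) == 0:
        raise ValueError("binary stack contains no solid voxels")
    d = np.asarray(binary.voxel_size, dtype=float)
    centers = (solid + 0.5) * d
    tree = cKDTree(centers)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1.0, size=(n_points, 3)) * (
        np.asarray(binary.shape, dtype=float) * d
    )
    dist, _ = tree.query(pts, workers=-1)
    return dist


def nearest_obstacle_distribution(
    binary: BinaryStack,
    n_points: int = DEFAULT_N_POINTS,
    seed: int | np.random.Generator | None = None,
    bin_edges: np.ndarray | None = None,
) -> DistanceDistribution:
    """Binned nearest-obstacle-distance distribution.

    Default bin width is one voxel (largest physical voxel dimension), from 0
    to the maximal observed distance; pass explicit ``bin_edges`` to compare
    several stacks on shared bins.
    """
    dist = nearest_obstacle_distances(binary, n_points=n_points, seed=seed)
    if bin_edges is None:
        width = float(max(binary.voxel_size))
        upper = max(dist.max(), width)
        bin_edges = np.arange(0.0, upper + width, width)
    hist, edges = np.histogram(dist, bins=bin_edges)
    probs = hist / hist.sum() if hist.sum() else hist.astype(float)
    return DistanceDistribution(bin_edges=edges, probabilities=probs,
                                n_points=n_points, distances=dist)


def shared_bin_edges(binaries: list[BinaryStack],
                     n_bins: int | None = None) -> np.ndarray:
    """Bin edges usable for all given stacks: width of one voxel of the
    coarsest stack, spanning the largest volume diagonal if n_bins not set."""
    width = max(float(max(b.voxel_size)) for b in binaries)
    if n_bins is None:
        diag = max(
            float(np.linalg.norm(np.asarray(b.shape) * np.asarray(b.voxel_size)))
            for b in binaries
        )
        n_bins = int(np.ceil(diag / width))
    return np.arange(0.0, (n_bins + 1) * width, width)[: n_bins + 1]


def distribution_correlation(a: DistanceDistribution,
                             b: DistanceDistribution) -> float:
    """Pearson correlation coefficient of two binned distance distributions.

    Distributions with different binning are rebinned from their raw
    distances (kept by :func:`nearest_obstacle_distribution`) onto shared
    edges of the coarser bin width.
    """
    if a.bin_edges.shape == b.bin_edges.shape and np.allclose(
        a.bin_edges, b.bin_edges
    ):
        pa, pb = a.probabilities, b.probabilities
    else:
        if a.distances is None or b.distances is None:
            raise ValueError(
                "distributions have different binning and no raw distances "
                "to rebin from"
            )
        width = max(np.diff(a.bin_edges).max(), np.diff(b.bin_edges).max())
        upper = max(a.distances.max(), b.distances.max())
        edges = np.arange(0.0, upper + width, width)
        pa, _ = np.histogram(a.distances, bins=edges, density=False)
        pb, _ = np.histogram(b.distances, bins=edges, density=False)
        pa = pa / pa.sum()
        pb = pb / pb.sum()
    if np.ptp(pa) == 0 or np.ptp(pb) == 0:
        raise ValueError("cannot correlate a zero-variance distribution")
    return float(pearsonr(pa, pb).statistic)


def segment_angle_distributions(
    network: LineNetwork,
    n_bins: int = 36,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Histograms of azimuthal (phi) and polar (theta) segment angles.

    Returns ``(phi_edges, phi_probs, theta_edges, theta_probs)``.  Optional
    per-segment weights (e.g. blind-spot visibility) allow comparing the
    angular makeup of the *visible* network to the full one.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    phi = network.azimuthal_angles
    theta = network.polar_angles
    phi_hist, phi_edges = np.histogram(
        phi, bins=n_bins, range=(0.0, 2.0 * np.pi), weights=weights
    )
    theta_hist, theta_edges = np.histogram(
        theta, bins=n_bins, range=(0.0, np.pi), weights=weights
    )
    phi_probs = phi_hist / phi_hist.sum() if phi_hist.sum() else phi_hist * 0.0
    theta_probs = (
        theta_hist / theta_hist.sum() if theta_hist.sum() else theta_hist * 0.0
    )
    return phi_edges, phi_probs, theta_edges, theta_probs


def intensity_histogram(
    stack: ImageStack,
    mask: BinaryStack | np.ndarray | None = None,
) -> np.ndarray:
    """256-bin histogram of voxel intensities B, optionally restricted to the
    solid (or fluid) phase via a boolean mask."""
    voxels = np.asarray(stack.voxels)
    if mask is not None:
        m = mask.voxels if isinstance(mask, BinaryStack) else np.asarray(mask)
        voxels = voxels[m.astype(bool)]
    return np.bincount(
        np.clip(voxels.astype(np.int64).ravel(), 0, 255), minlength=256
    )[:256]
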