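"""Core data containers for fiber-network reconstruction.

Coordinate convention: arrays are indexed ``[x, y, z]`` (0-based), with z the
optical/scan axis.  Continuous coordinates are measured in voxel units where
voxel ``(i, j, k)`` spans the cube ``[i, i+1) x [j, j+1) x [k, k+1)`` and has
its center at ``(i+0.5, j+0.5, k+0.5)``.  Physical positions are obtained by
multiplying with the per-axis voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineNetwork",
    "ImagingParams",
    "ImageStack",
    "BinaryStack",
    "Template",
    "MismatchField",
    "NeighborCountDistribution",
    "DistanceDistribution",
]

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class LineNetwork:
    """Ground-truth set of straight fiber segments in continuous 3D space.

    Segments are stored as an ``(n, 2, 3)`` array of (start, end) points in
    voxel units of the target grid.  Segments may extend past the volume
    boundary; only the in-volume part is voxelized.
    """

    segments: np.ndarray  # (n, 2, 3) float
    fiber_length: float
    volume_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float).reshape(-1, 2, 3)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def directions(self) -> np.ndarray:
        """Unit direction vectors, shape (n, 3)."""
        d = self.segments[:, 1] - self.segments[:, 0]
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(norm == 0, 1.0, norm)

    @property
    def polar_angles(self) -> np.ndarray:
        """Polar angle theta (radians) of each segment vs. the z-axis."""
        ct = np.abs(self.directions[:, 2])
        return np.arccos(np.clip(ct, -1.0, 1.0))

    @property
    def azimuthal_angles(self) -> np.ndarray:
        """Azimuthal angle phi (radians) in [0, 2*pi)."""
        d = self.directions
        return np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)


@dataclass
class ImagingParams:
    """Confocal imaging model parameters.

    psf_sigma : Gaussian PSF standard deviations (sx, sy, sz) in voxels;
        axial blur is typically largest (sz > sx = sy).
    blindspot_enabled : apply the reflection-mode darkening of steep fibers.
    blindspot_exponent : exponent p of the weight (sin theta)**p; p = 0
        disables the darkening even when enabled.
    noise_sigma : standard deviation of additive Gaussian intensity noise.
    peak / background : target core and background intensities before noise.
    """

    psf_sigma: tuple[float, float, float] = (1.0, 1.0, 3.0)
    blindspot_enabled: bool = True
    blindspot_exponent: float = 2.0
    noise_sigma: float = 10.0
    peak: float = 200.0
    background: float = 15.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma components must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.blindspot_exponent < 0:
            raise ValueError("blindspot_exponent must be >= 0")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class ImageStack:
    """3D grayscale volume with physical voxel dimensions (nm)."""

    voxels: np.ndarray  # (nx, ny, nz)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ImageStack requires a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def global_mean(self) -> float:
        return float(self.voxels.mean())


@dataclass
class BinaryStack:
    """3D boolean volume; True = solid phase (fiber), False = fluid phase."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("BinaryStack requires a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_solid(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Template:
    """Mean-subtracted, unit-normalized 2D fiber cross-section pattern.

    The pattern is an s x s array (s odd) whose entries sum of squares is 1
    after finalization; the central entry is positive (bright fiber core) and
    the outermost ring contains at least one non-positive entry (dark border).
    """

    pattern: np.ndarray
    scan_axis: str
    global_mean: float

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        s = self.pattern.shape[0]
        if self.pattern.shape != (s, s) or s % 2 == 0 or s < 3:
            raise ValueError("template pattern must be square with odd size >= 3")
        if self.scan_axis not in AXES:
            raise ValueError(f"scan_axis must be one of {sorted(AXES)}")

    @property
    def size(self) -> int:
        return self.pattern.shape[0]


@dataclass
class MismatchField:
    """Per-pixel mismatch distances D for one search plane.

    D is the Euclidean distance between the unit-normalized search section and
    the template vector, hence D lies in [0, 2].  Pixels in the border margin
    (no full window) carry the maximal mismatch 2.
    """

    values: np.ndarray
    plane_index: int = 0


@dataclass
class NeighborCountDistribution:
    """Histogram over n = 0..26 of solid 26-neighbors per solid voxel."""

    counts: np.ndarray  # length 27

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (27,):
            raise ValueError("counts must have length 27")

    @property
    def n_solid(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros(27)
        return self.counts / tot

    @property
    def mode(self) -> int:
        """Most probable neighbor count; -1 for an empty distribution.

        When several counts tie for the maximum, the tie is resolved in favor
        of n = 3 if it participates (boundary of the acceptable threshold
        interval), otherwise the smallest tied value is returned.
        """
        if self.n_solid == 0:
            return -1
        modes = np.flatnonzero(self.counts == self.counts.max())
        return 3 if 3 in modes else int(modes[0])


@dataclass
class DistanceDistribution:
    """Binned distribution of nearest-obstacle distances (pore-size proxy)."""

    bin_edges: np.ndarray  # physical lengths, strictly increasing
    probabilities: np.ndarray
    n_points: int
    distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be >= 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_distance(self) -> float:
        """Mean of the raw distances if kept, else the binned approximation."""
        if self.distances is not None:
            return float(np.mean(self.distances))
        return float(np.sum(self.bin_centers * self.probabilities))
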