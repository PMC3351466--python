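"""End-to-end parameter-free reconstruction pipeline.

``FiberReconstructor`` is a scikit-learn-style transformer: ``fit`` learns
the matching templates and the mismatching threshold from the stack itself,
``transform`` produces the binarized + skeletonized volume.  ``run_pipeline``
wraps it for file-to-file use with a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import BinaryStack, ImageStack
from .matching import combine_scans, scan_axis
from .templates import DEFAULT_INITIAL_SIZE, DEFAULT_N_SAMPLES, build_template
from .threshold import (
    TARGET_NEIGHBOR_MODE,
    _Pipeline,
    neighbor_count_distribution,
    optimize_threshold,
)

__all__ = ["FiberReconstructor", "ReconstructionConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Scan directions per imaging mode.  The blind-spot effect makes steep
#: fibers invisible in reflection microscopy, so the z-scan adds nothing
#: there; fluorescence images need all three.
MODE_AXES = {"reflection": ("x", "y"), "fluorescence": ("x", "y", "z")}


class FiberReconstructor(TransformerMixin, BaseEstimator):
    """Parameter-free binarization + skeletonization of fiber-network stacks.

    Parameters
    ----------
    mode : 'reflection' or 'fluorescence'
        Imaging modality; decides which plane scans run (x/y vs. x/y/z).
    threshold : float or None
        Mismatching threshold override in (0, 2).  ``None`` (default, the
        parameter-free path) optimizes it so the reconstruction's
        neighbor-count mode equals ``target_neighbor_mode``.
    template_size : int
        Initial template size s0 (odd); shrunk automatically per axis.
    n_samples : int
        Random sections averaged per template.
    target_neighbor_mode : int
        Topology signature for the threshold search (3 for line networks).
    random_state : int or None
        Seed for template-section sampling.

    Attributes
    ----------
    templates_ : dict of axis -> Template
    threshold_ : float, the threshold actually used
    neighbor_counts_ : histogram over n=0..26 for the final reconstruction
    n_solid_per_axis_ : dict of axis -> solid voxel count of that scan
    """

    def __init__(
        self,
        mode: str = "reflection",
        threshold: float | None = None,
        template_size: int = DEFAULT_INITIAL_SIZE,
        n_samples: int = DEFAULT_N_SAMPLES,
        target_neighbor_mode: int = TARGET_NEIGHBOR_MODE,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.threshold = threshold
        self.template_size = template_size
        self.n_samples = n_samples
        self.target_neighbor_mode = target_neighbor_mode
        self.random_state = random_state

    def _as_stack(self, X) -> ImageStack:
        if isinstance(X, ImageStack):
            return X
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected a 3D intensity volume")
        return ImageStack(voxels=X)

    def fit(self, X, y=None):
        """Learn templates and (unless overridden) the mismatching threshold
        from the stack ``X`` (3D array or ImageStack)."""
        if self.mode not in MODE_AXES:
            raise ValueError(f"mode must be one of {sorted(MODE_AXES)}")
        stack = self._as_stack(X)
        rng = np.random.default_rng(self.random_state)
        self.templates_ = {
            ax: build_template(
                stack, scan_axis=ax, seed=rng,
                s0=self.template_size, n_samples=self.n_samples,
            )
            for ax in MODE_AXES[self.mode]
        }
        tlist = list(self.templates_.values())
        if self.threshold is not None:
            if not 0.0 < self.threshold < 2.0:
                raise ValueError("threshold override must lie in (0, 2)")
            self.threshold_ = float(self.threshold)
            self._fit_pipeline = _Pipeline(stack, tlist)
            logger.info("threshold override %.4f (optimization skipped)",
                        self.threshold_)
        else:
            self.threshold_, self._fit_pipeline = optimize_threshold(
                stack, tlist,
                target_mode=self.target_neighbor_mode,
                return_pipeline=True,
            )
        self._fit_voxels = stack.voxels
        return self

    def transform(self, X) -> np.ndarray:
        """Reconstruct the stack: returns a 3D boolean skeleton volume."""
        check_is_fitted(self, "threshold_")
        stack = self._as_stack(X)
        if stack.voxels is self._fit_voxels:
            scans = [
                scan_axis(stack, t, self.threshold_, precomputed_mismatch=v)
                for t, v in zip(self._fit_pipeline.templates,
                                self._fit_pipeline.volumes)
            ]
        else:
            scans = [
                scan_axis(stack, t, self.threshold_)
                for t in self.templates_.values()
            ]
        recon = combine_scans(scans)
        self.n_solid_per_axis_ = {
            ax: s.n_solid for ax, s in zip(self.templates_, scans)
        }
        self.neighbor_counts_ = neighbor_count_distribution(recon).counts
        return recon.voxels

    def reconstruct(self, stack: ImageStack) -> BinaryStack:
        """Convenience: fit + transform returning a BinaryStack."""
        self.fit(stack)
        voxels = self.transform(stack)
        return BinaryStack(voxels=voxels, voxel_size=stack.voxel_size)


@dataclass
class ReconstructionConfig:
    """Configuration echo for the file-to-file pipeline.

    When ``threshold`` is None the parameter-free path runs: the template and
    the mismatching threshold are derived from the input stack alone.
    """

    mode: str = "reflection"
    template_size: int = DEFAULT_INITIAL_SIZE
    n_samples: int = DEFAULT_N_SAMPLES
    threshold: float | None = None
    target_neighbor_mode: int = TARGET_NEIGHBOR_MODE
    seed: int | None = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReconstructionConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**doc)
        if cfg.voxel_size is not None:
            cfg.voxel_size = tuple(cfg.voxel_size)
        return cfg


def run_pipeline(
    config: ReconstructionConfig,
    in_path: str | Path,
    out_path: str | Path,
) -> dict:
    """Reconstruct a stack file to a skeleton file plus JSON report.

    Stages: read stack -> build templates per axis -> optimize threshold
    (unless overridden) -> scan axes -> OR-combine -> write skeleton + report
    (threshold, neighbor histogram, solid fraction, per-axis counts, config).
    """
    from .io import read_stack, write_stack

    stack = read_stack(in_path, voxel_size=config.voxel_size)
    est = FiberReconstructor(
        mode=config.mode,
        threshold=config.threshold,
        template_size=config.template_size,
        n_samples=config.n_samples,
        target_neighbor_mode=config.target_neighbor_mode,
        random_state=config.seed,
    )
    try:
        recon = est.reconstruct(stack)
    except Exception as exc:  # annotate the failing stage for CLI users
        raise RuntimeError(f"reconstruction failed: {exc}") from exc
    write_stack(recon, out_path)

    from .datatypes import NeighborCountDistribution

    counts = est.neighbor_counts_
    mode_n = NeighborCountDistribution(counts=counts).mode
    report = {
        "input": str(in_path),
        "output": str(out_path),
        "threshold": est.threshold_,
        "threshold_optimized": config.threshold is None,
        "neighbor_count_histogram": counts.tolist(),
        "neighbor_count_mode": mode_n,
        "n_solid": int(recon.n_solid),
        "solid_fraction": float(recon.n_solid / recon.voxels.size),
        "n_solid_per_axis": est.n_solid_per_axis_,
        "template_sizes": {ax: t.size for ax, t in est.templates_.items()},
        "config": asdict(config),
    }
    report_path = Path(out_path).with_suffix(".report.json")
    report_path.write_text(json.dumps(report, indent=1))
    return report
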