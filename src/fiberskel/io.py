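"""Stack, template, and network (de)serialization.

Image and binary stacks travel as multi-page grayscale TIFF (pages along the
optical z-axis) or NPZ volumes; templates as NPZ; ground-truth networks and
reports as YAML/JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .datatypes import BinaryStack, ImageStack, LineNetwork, Template

__all__ = [
    "read_stack",
    "write_stack",
    "save_template",
    "load_template",
    "save_network",
    "load_network",
]


def _to_internal(pages: np.ndarray) -> np.ndarray:
    # TIFF layout is (z, y, x); internally we index [x, y, z].
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def _to_pages(voxels: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(voxels.transpose(2, 1, 0))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageStack:
    """Load a multi-page grayscale TIFF (8/16-bit) or NPZ volume.

    16-bit input is rescaled to the [0, 255] working range.  NPZ files must
    contain a ``voxels`` array and may carry their own ``voxel_size``.
    """
    path = Path(path)
    if path.suffix.lower() == ".npz":
        data = np.load(path)
        vox = data["voxels"]
        if "voxel_size" in data:
            voxel_size = tuple(float(v) for v in data["voxel_size"])
        if vox.ndim != 3:
            raise ValueError(f"{path}: NPZ volume must be 3D, got {vox.ndim}D")
        return ImageStack(voxels=vox, voxel_size=voxel_size)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError(f"{path}: single-page TIFF is not a 3D stack")
    if pages.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale multi-page TIFF, got shape "
            f"{pages.shape} (RGB and multi-channel input are unsupported)"
        )
    if pages.dtype == np.uint16:
        pages = (pages.astype(np.float64) * (255.0 / 65535.0)).round().astype(
            np.uint8
        )
    elif pages.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported TIFF dtype {pages.dtype}")
    return ImageStack(voxels=_to_internal(pages), voxel_size=voxel_size)


def write_stack(stack: ImageStack | BinaryStack, path: str | Path) -> Path:
    """Write a stack as lossless multi-page TIFF (or NPZ by extension).

    Binary stacks are written as {0, 255} 8-bit grayscale.
    """
    path = Path(path)
    if isinstance(stack, BinaryStack):
        voxels = stack.voxels.astype(np.uint8) * 255
    else:
        voxels = np.asarray(stack.voxels)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(path, voxels=voxels,
                            voxel_size=np.asarray(stack.voxel_size))
        return path
    tifffile.imwrite(path, _to_pages(voxels.astype(np.uint8)),
                     photometric="minisblack")
    return path


def save_template(template: Template, path: str | Path) -> Path:
    path = Path(path)
    np.savez(path, pattern=template.pattern,
             scan_axis=np.array(template.scan_axis),
             global_mean=np.array(template.global_mean))
    return path


def load_template(path: str | Path) -> Template:
    data = np.load(path)
    return Template(pattern=data["pattern"],
                    scan_axis=str(data["scan_axis"]),
                    global_mean=float(data["global_mean"]))


def save_network(network: LineNetwork, path: str | Path,
                 extra: dict | None = None) -> Path:
    """Ground-truth sidecar: segment endpoints, fiber length, volume shape
    plus optional parameter echo, as YAML or JSON by extension."""
    path = Path(path)
    doc = {
        "volume_shape": [int(n) for n in network.volume_shape],
        "fiber_length": float(network.fiber_length),
        "segments": np.asarray(network.segments).reshape(-1, 6).tolist(),
    }
    if extra:
        doc["parameters"] = extra
    text = (
        json.dumps(doc, indent=1)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(doc)
    )
    path.write_text(text)
    return path


def load_network(path: str | Path) -> LineNetwork:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    segments = np.asarray(doc["segments"], dtype=float).reshape(-1, 2, 3)
    return LineNetwork(segments=segments,
                       fiber_length=float(doc["fiber_length"]),
                       volume_shape=tuple(doc["volume_shape"]))
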