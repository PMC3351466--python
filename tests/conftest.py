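"""Shared fixtures: small ground-truth-known surrogates built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from fiberskel.datatypes import ImagingParams
from fiberskel.synthetic import generate_mikado, render_stack, voxelize


@pytest.fixture(scope="session")
def small_surrogate():
    """A 64^3 surrogate with known ground truth: moderate density, known-good
    imaging conditions.  Returns (network, truth BinaryStack, ImageStack)."""
    network = generate_mikado((64, 64, 64), n_lines=60, fiber_length=40,
                              seed=11)
    truth = voxelize(network)
    params = ImagingParams(psf_sigma=(0.8, 0.8, 2.0), noise_sigma=6.0)
    stack = render_stack(truth, network, params, mode="reflection", seed=12)
    return network, truth, stack


@pytest.fixture(scope="session")
def standard_surrogate():
    """A 96^3 surrogate used for pipeline-level checks."""
    network = generate_mikado((96, 96, 96), n_lines=180, fiber_length=50,
                              seed=21)
    truth = voxelize(network)
    params = ImagingParams(psf_sigma=(1.0, 1.0, 2.5), noise_sigma=8.0)
    stack = render_stack(truth, network, params, mode="reflection", seed=22)
    return network, truth, stack


@pytest.fixture(scope="session")
def battery_results():
    """Full-pipeline results over the standard surrogate battery (shared by
    the fidelity and topology acceptance checks; ~3 minutes)."""
    from fiberskel.validation import run_battery

    return run_battery(seed=1, n_points=100_000)


def rng_for(case: int) -> np.random.Generator:
    return np.random.default_rng(900_000 + case)
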