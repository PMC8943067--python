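"""Shared fixtures: tiny CMP images and noiseless simulated samples."""

from __future__ import annotations

import numpy as np
import pytest

from toponome import SimConfig, simulate_field
from toponome.image_prep import CMPImage, bitstring_to_code
from toponome.synthetic import SampleMeta


@pytest.fixture
def moderate_library_8():
    """Phenotypes with moderate expression on every marker, so each channel
    carries registration signal."""
    return [
        np.array([0.3, 0.8, 0.8, 0.2, 0.2, 0.3, 0.2, 0.9]),
        np.array([0.3, 0.2, 0.2, 0.8, 0.8, 0.2, 0.3, 0.9]),
        np.array([0.4, 0.2, 0.3, 0.2, 0.2, 0.8, 0.8, 0.9]),
    ]


@pytest.fixture
def noiseless_sample(moderate_library_8):
    """Noiseless, bleed-free misregistered sample: the preprocessing chain
    must reproduce the planted truth exactly."""
    cfg = SimConfig(
        field_size=160, n_cells=8, n_markers=8, noise_sd=0.0,
        bleach_residual=0.0, shift_max=2, af_puncta_rate=2.0,
        phenotype_library=moderate_library_8, seed=11,
    )
    return cfg, simulate_field(cfg, SampleMeta("S1", "Vehicle", "F"))


def make_cmp_image(bitstrings: dict[tuple[int, int], str], shape, n_markers, margin=0):
    """Build a CMPImage from explicit per-pixel bitstrings (tests only)."""
    codes = np.zeros(shape, dtype=np.uint32)
    for (r, c), bs in bitstrings.items():
        codes[r, c] = bitstring_to_code(bs)
    return CMPImage(codes=codes, n_markers=n_markers, margin=margin)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
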