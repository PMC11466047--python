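"""Shared fixtures and independent oracles.

The 1D oracle in :func:`numeric_blurred_template` recomputes the blurred
striation template by brute-force discrete convolution of the hard-edged
box pattern with a sampled Gaussian, independently of the closed-form
normal-CDF route used inside the package.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from myoshg import Image, LatticeParams, generate_lattice_image


def numeric_blurred_template(
    u: np.ndarray,
    period_um: float,
    aband_um: float,
    mline_um: float,
    sigma_um: float,
    dx: float = 1e-4,
) -> np.ndarray:
    """Brute-force blurred template: fine sampling + discrete convolution."""
    span = 4 * sigma_um + period_um
    lo, hi = float(np.min(u)) - span, float(np.max(u)) + span
    grid = np.arange(lo, hi, dx)
    gm = np.mod(grid, period_um)
    c = period_um / 2
    hard = (
        (np.abs(gm - c) <= aband_um / 2) & (np.abs(gm - c) > mline_um / 2)
    ).astype(float)
    if sigma_um > 0:
        half = int(np.ceil(6 * sigma_um / dx))
        k = np.exp(-0.5 * ((np.arange(-half, half + 1) * dx) / sigma_um) ** 2)
        k /= k.sum()
        blurred = np.convolve(hard, k, mode="same")
    else:
        blurred = hard
    return np.interp(np.asarray(u, float), grid, blurred)


def make_textured_lattice(
    params: LatticeParams, amplitude: float = 0.15, texture_seed: int = 5
) -> Image:
    """Lattice image with a smooth multiplicative envelope.

    The envelope gives the otherwise one-dimensional striation pattern
    enough 2D structure for translational registration to be well-posed.
    """
    img, _ = generate_lattice_image(params, noiseless=True)
    rng = np.random.default_rng(texture_seed)
    tex = ndimage.gaussian_filter(rng.random(img.shape), 8)
    tex = 1 + amplitude * (tex - tex.mean()) / np.abs(tex - tex.mean()).max()
    return Image(np.clip(img.pixels * tex, 0, None), img.pixel_um, img.channel)


@pytest.fixture
def default_lattice():
    """Noisy double-band lattice at the default study geometry."""
    params = LatticeParams(seed=1)
    image, gt = generate_lattice_image(params)
    return params, image, gt


@pytest.fixture
def noiseless_lattice():
    params = LatticeParams()
    image, gt = generate_lattice_image(params, noiseless=True)
    return params, image, gt
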