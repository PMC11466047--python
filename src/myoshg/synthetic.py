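"""Synthetic ground-truth image generators.

Two generators stand in for tissue-section data so every downstream stage
can be tested against exact ground truth:

* :func:`generate_lattice_image` renders the striated myosin lattice seen
  in forward-SHG images of cardiomyocytes. One spatial period (the
  sarcomere length) contains a bright A-band (the myosin rod region, the
  only part with SHG contrast) split by a narrow dark M-line gap at its
  centre, and a dark I-band centred on the Z-line. Optical blur is an
  isotropic Gaussian PSF; photon statistics are Poisson. When the PSF is
  narrow enough to resolve the two halves of the A-band the image shows a
  "double-band" pattern; otherwise a "single-band" pattern.

* :func:`generate_tissue_layout` places non-overlapping cardiomyocyte
  cross-sections (irregular convex blobs) and capillaries (small discs) in
  a field of view, emitting an autofluorescence-like intensity image plus
  an exact instance mask set with categories.

Both are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.special import ndtr  # standard normal CDF, vectorized
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .datatypes import (
    CATEGORY_CAPILLARY,
    CATEGORY_CARDIOMYOCYTE,
    Image,
    InstanceMaskSet,
)
from .exceptions import ParameterError, PlacementError

#: FWHM -> standard deviation for a Gaussian, 1 / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: fractional dip depth separating the double- from the single-band regime
REGIME_DIP_FRACTION = 0.01


@dataclass(frozen=True)
class LatticeParams:
    """Geometry, optics and photon budget of a striated-lattice image.

    Defaults: sarcomere period 1.84 um (adult murine left ventricle),
    A-band 1.6 um and M-line 0.17 um (vertebrate striated-muscle
    literature values), pixel 0.04 um, Gaussian PSF FWHM 0.25 um.
    """

    period_um: float = 1.84
    aband_um: float = 1.6
    mline_um: float = 0.17
    orientation_deg: float = 0.0
    psf_fwhm_um: float = 0.25
    pixel_um: float = 0.04
    shape_px: tuple[int, int] = (160, 384)
    peak_photons: float = 200.0
    background_photons: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.mline_um):
            raise ParameterError(f"violated 0 < mline_um: mline_um={self.mline_um}")
        if not (self.mline_um < self.aband_um):
            raise ParameterError(
                f"violated mline_um < aband_um: {self.mline_um} >= {self.aband_um}"
            )
        if not (self.aband_um < self.period_um):
            raise ParameterError(
                f"violated aband_um < period_um: {self.aband_um} >= {self.period_um}"
            )
        if not (self.pixel_um <= self.period_um / 4):
            raise ParameterError(
                "violated pixel_um <= period_um/4 (striation Nyquist): "
                f"{self.pixel_um} > {self.period_um / 4}"
            )
        if not (self.peak_photons > self.background_photons >= 0):
            raise ParameterError(
                "violated peak_photons > background_photons >= 0: "
                f"peak={self.peak_photons}, background={self.background_photons}"
            )
        if not (self.psf_fwhm_um >= 0):
            raise ParameterError(f"violated psf_fwhm_um >= 0: {self.psf_fwhm_um}")
        if min(self.shape_px) < 8:
            raise ParameterError(f"shape_px must be at least 8x8, got {self.shape_px}")


@dataclass(frozen=True)
class TissueLayoutParams:
    """Layout of a synthetic cross-sectional tissue field of view.

    Defaults give ~20% area coverage at 80x80 um so rejection sampling
    converges quickly: 6 cardiomyocytes of mean radius 8 um, 5 capillaries
    of mean radius 2.5 um, pixel 0.2 um.
    """

    n_cardiomyocytes: int = 6
    n_capillaries: int = 5
    cm_radius_um: float = 8.0
    cm_radius_jitter: float = 0.25
    cap_radius_um: float = 2.5
    cap_radius_jitter: float = 0.2
    fov_um: tuple[float, float] = (80.0, 80.0)
    pixel_um: float = 0.2
    seed: int = 0
    max_attempts_per_object: int = 500

    def validate(self) -> None:
        if self.n_cardiomyocytes < 0 or self.n_capillaries < 0:
            raise ParameterError("violated counts >= 0")
        if not (self.cap_radius_um < self.cm_radius_um):
            raise ParameterError(
                "violated cap_radius_um < cm_radius_um: "
                f"{self.cap_radius_um} >= {self.cm_radius_um}"
            )
        if not (self.pixel_um > 0 and min(self.fov_um) > 0):
            raise ParameterError("violated pixel_um > 0 and fov_um > 0")
        for name, j in (
            ("cm_radius_jitter", self.cm_radius_jitter),
            ("cap_radius_jitter", self.cap_radius_jitter),
        ):
            if not (0 <= j < 1):
                raise ParameterError(f"violated 0 <= {name} < 1: {j}")


@dataclass
class GroundTruth:
    """Exact generating parameters recorded alongside synthetic outputs.

    Lattice fields: ``true_period_um``, ``band_regime``,
    ``true_minima_positions_um`` (I-band/Z-line centres along the myofibril
    axis, um from the top-left pixel centre projected onto the axis).
    Tissue fields: instance counts, per-label categories and areas.
    """

    true_period_um: Optional[float] = None
    band_regime: Optional[str] = None  # 'double' | 'single'
    true_minima_positions_um: Optional[np.ndarray] = None
    orientation_deg: Optional[float] = None
    n_cardiomyocytes: Optional[int] = None
    n_capillaries: Optional[int] = None
    instance_areas_um2: dict[int, float] = field(default_factory=dict)
    instance_categories: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {}
        if self.true_period_um is not None:
            d["true_period_um"] = self.true_period_um
            d["band_regime"] = self.band_regime
            d["true_minima_positions_um"] = (
                np.asarray(self.true_minima_positions_um).tolist()
            )
            d["orientation_deg"] = self.orientation_deg
        if self.n_cardiomyocytes is not None:
            d["n_cardiomyocytes"] = self.n_cardiomyocytes
            d["n_capillaries"] = self.n_capillaries
            d["instance_areas_um2"] = {
                str(k): v for k, v in sorted(self.instance_areas_um2.items())
            }
            d["instance_categories"] = {
                str(k): v for k, v in sorted(self.instance_categories.items())
            }
        return d


def striation_template(
    u_um: np.ndarray,
    period_um: float,
    aband_um: float,
    mline_um: float,
    psf_sigma_um: float,
) -> np.ndarray:
    """Noiseless blurred axial intensity template, evaluated in closed form.

    The unblurred template over one period [0, L) is 1 on the A-band
    (centred at L/2) except a 0 gap of width ``mline_um`` at its centre,
    and 0 on the I-band. Convolution of the periodic box pattern with a
    Gaussian of standard deviation ``psf_sigma_um`` is a sum of normal-CDF
    differences over neighbouring periods.

    Returns values in [0, 1] for any ``u_um`` (um along the myofibril axis).
    """
    u = np.asarray(u_um, dtype=np.float64)
    L, a, m = period_um, aband_um, mline_um
    um = np.mod(u, L)
    out = np.zeros_like(um)
    if psf_sigma_um <= 0:
        c = L / 2
        out = (
            (np.abs(um - c) <= a / 2) & (np.abs(um - c) > m / 2)
        ).astype(np.float64)
        return out
    s = psf_sigma_um
    # +-k periods cover the Gaussian tails (4 sigma << 3 periods for any
    # PSF that leaves striation contrast at all)
    kmax = max(3, int(math.ceil(4 * s / L)) + 1)
    for k in range(-kmax, kmax + 1):
        c = L / 2 + k * L
        out += ndtr((um - (c - a / 2)) / s) - ndtr((um - (c + a / 2)) / s)
        out -= ndtr((um - (c - m / 2)) / s) - ndtr((um - (c + m / 2)) / s)
    return out


def classify_band_regime(
    period_um: float,
    aband_um: float,
    mline_um: float,
    psf_sigma_um: float,
    n_samples: int = 8192,
) -> tuple[str, float]:
    """Band regime of the blurred template and the M-line dip depth.

    'double' iff the blurred template has a local minimum at the M-line
    centre (u = L/2) whose depth below the lower of the two flanking local
    maxima exceeds ``REGIME_DIP_FRACTION`` of the template dynamic range.

    Returns ``(regime, dip_depth_fraction)``.
    """
    L = period_um
    u = np.arange(n_samples) * (L / n_samples)
    v = striation_template(u, L, aband_um, mline_um, psf_sigma_um)
    dyn = float(v.max() - v.min())
    if dyn <= 0:
        return "single", 0.0
    c = n_samples // 2  # u = L/2 exactly
    # dip depth below the lower of the two flanking maxima between the
    # I-band centres (0 and L); robust to flat plateaus at near-zero blur
    left_max = float(v[1:c].max())
    right_max = float(v[c + 1 :].max())
    depth = (min(left_max, right_max) - float(v[c])) / dyn
    return ("double" if depth > REGIME_DIP_FRACTION else "single"), float(depth)


def generate_lattice_image(
    params: LatticeParams, *, noiseless: bool = False
) -> tuple[Image, GroundTruth]:
    """Render a striated lattice image with exact ground truth.

    Pipeline: the periodic axial template (A-band bright, M-line and
    I-band dark) is extruded perpendicular to the myofibril axis, rotated
    by ``orientation_deg``, blurred by the Gaussian PSF (evaluated in
    closed form along the axial coordinate, which equals the isotropic 2D
    blur because the pattern is constant perpendicular to the axis),
    linearly scaled to ``[background_photons, peak_photons]``, and
    Poisson-sampled with the given seed.

    With ``noiseless=True`` the Poisson step is skipped and the expected
    photon count is returned (debug/oracle path).
    """
    params.validate()
    h, w = params.shape_px
    sigma = params.psf_fwhm_um * FWHM_TO_SIGMA
    theta = math.radians(params.orientation_deg)
    y, x = np.mgrid[0:h, 0:w].astype(np.float64) * params.pixel_um
    u = math.cos(theta) * x + math.sin(theta) * y
    tmpl = striation_template(
        u, params.period_um, params.aband_um, params.mline_um, sigma
    )
    # scale template range (from a dense 1D evaluation, not the finite
    # image) to [background, peak] expected photons
    u1 = np.arange(4096) * (params.period_um / 4096)
    v1 = striation_template(
        u1, params.period_um, params.aband_um, params.mline_um, sigma
    )
    lo, hi = float(v1.min()), float(v1.max())
    if hi - lo <= 0:
        mean = np.full_like(tmpl, params.background_photons)
    else:
        mean = params.background_photons + (tmpl - lo) / (hi - lo) * (
            params.peak_photons - params.background_photons
        )
    mean = np.clip(mean, 0.0, None)
    if noiseless:
        pixels = mean
    else:
        rng = np.random.default_rng(params.seed)
        pixels = rng.poisson(mean).astype(np.float64)
    image = Image(pixels=pixels, pixel_um=params.pixel_um, channel="F-SHG")
    regime, _ = classify_band_regime(
        params.period_um, params.aband_um, params.mline_um, sigma
    )
    u_max = float(u.max())
    minima = np.arange(0.0, u_max + 1e-9, params.period_um)
    gt = GroundTruth(
        true_period_um=params.period_um,
        band_regime=regime,
        true_minima_positions_um=minima,
        orientation_deg=params.orientation_deg,
    )
    return image, gt


def _convex_blob_coords(
    rng: np.random.Generator,
    cy: float,
    cx: float,
    radius_px: float,
    jitter: float,
    shape: tuple[int, int],
    n_vertices: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of an irregular convex polygon around (cy, cx)."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    rad = radius_px * (1 + jitter * rng.uniform(-1, 1, n_vertices))
    pts = np.column_stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)])
    hull = ConvexHull(pts)
    v = pts[hull.vertices]
    return draw_polygon(v[:, 0], v[:, 1], shape=shape)


def generate_tissue_layout(
    params: TissueLayoutParams,
) -> tuple[Image, InstanceMaskSet, GroundTruth]:
    """Place cardiomyocytes and capillaries by no-overlap dart throwing.

    Cardiomyocytes are irregular convex blobs (labels 1..n_cm), capillaries
    small discs (labels n_cm+1..n_cm+n_cap); instances are separated by at
    least one background pixel and lie fully inside the FOV. The intensity
    image is autofluorescence-like (textured bright cardiomyocyte
    interiors, dark capillary lumens with a bright rim) and cosmetic; the
    masks and counts carry the contract.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h = int(round(params.fov_um[0] / params.pixel_um))
    w = int(round(params.fov_um[1] / params.pixel_um))
    label_map = np.zeros((h, w), dtype=np.uint16)
    categories: dict[int, str] = {}
    areas_px: dict[int, int] = {}

    def try_place(label: int, category: str) -> None:
        r_um = (
            params.cm_radius_um
            if category == CATEGORY_CARDIOMYOCYTE
            else params.cap_radius_um
        )
        jit = (
            params.cm_radius_jitter
            if category == CATEGORY_CARDIOMYOCYTE
            else params.cap_radius_jitter
        )
        r_px = r_um / params.pixel_um
        margin = r_px * (1 + jit) + 2
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"object radius {r_um} um too large for FOV {params.fov_um} um"
            )
        for _ in range(params.max_attempts_per_object):
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            if category == CATEGORY_CARDIOMYOCYTE:
                rr, cc = _convex_blob_coords(rng, cy, cx, r_px, jit, (h, w))
            else:
                rad = r_px * (1 + jit * rng.uniform(-1, 1))
                rr, cc = draw_disk((cy, cx), rad, shape=(h, w))
            if len(rr) == 0:
                continue
            cand = np.zeros((h, w), dtype=bool)
            cand[rr, cc] = True
            # 1-px guard ring keeps instances disjoint under any connectivity
            if np.any(ndimage.binary_dilation(cand) & (label_map > 0)):
                continue
            label_map[rr, cc] = label
            categories[label] = category
            areas_px[label] = len(rr)
            return
        raise PlacementError(
            "placement budget exhausted after "
            f"{params.max_attempts_per_object} attempts for {category} {label}; "
            "lower the object density or radii"
        )

    label = 0
    for _ in range(params.n_cardiomyocytes):
        label += 1
        try_place(label, CATEGORY_CARDIOMYOCYTE)
    for _ in range(params.n_capillaries):
        label += 1
        try_place(label, CATEGORY_CAPILLARY)

    # AF-like appearance: bright textured cardiomyocytes, capillary rims
    mean = np.full((h, w), 20.0)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
    tmax = max(float(np.abs(texture).max()), 1e-12)
    for k, cat in categories.items():
        sel = label_map == k
        if cat == CATEGORY_CARDIOMYOCYTE:
            mean[sel] = 120.0 + 25.0 * texture[sel] / tmax
        else:
            interior = ndimage.binary_erosion(sel, iterations=3)
            mean[sel] = 180.0
            mean[interior] = 12.0
    pixels = rng.poisson(np.clip(mean, 0, None)).astype(np.float64)
    image = Image(pixels=pixels, pixel_um=params.pixel_um, channel="AF")
    masks = InstanceMaskSet(
        label_map=label_map, categories=categories, pixel_um=params.pixel_um
    )
    gt = GroundTruth(
        n_cardiomyocytes=params.n_cardiomyocytes,
        n_capillaries=params.n_capillaries,
        instance_areas_um2={
            k: a * params.pixel_um**2 for k, a in areas_px.items()
        },
        instance_categories=dict(categories),
    )
    return image, masks, gt
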