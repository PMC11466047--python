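"""Core in-memory containers shared by all modules.

Conventions
-----------
* Physical lengths are micrometres (um), areas um^2, densities um^-2.
* Pixel coordinates are 0-based (x = column, y = row); physical positions
  are measured in um from the centre of the top-left pixel.
* Angles are degrees in (-90, 90], measured from the +x (column) axis
  toward the +y (row) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError

VALID_CHANNELS = ("F-SHG", "B-SHG", "AF", "IF")

CATEGORY_CARDIOMYOCYTE = "cardiomyocyte"
CATEGORY_CAPILLARY = "capillary"
VALID_CATEGORIES = (CATEGORY_CARDIOMYOCYTE, CATEGORY_CAPILLARY)

LABEL_IBAND = "iband"
LABEL_ABAND_INTERNAL = "aband_internal"


@dataclass
class Image:
    """A 2D grayscale intensity image with physical pixel size.

    Parameters
    ----------
    pixels : 2D float array, non-negative intensities (photon counts or a.u.)
    pixel_um : pixel size in um/px (isotropic)
    channel : acquisition channel tag, one of ``F-SHG, B-SHG, AF, IF``
    """

    pixels: np.ndarray
    pixel_um: float
    channel: str = "F-SHG"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 8:
            raise ParameterError(
                f"image must be at least 8x8 px, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ParameterError("pixel intensities must be finite and non-negative")
        if not (self.pixel_um > 0):
            raise ParameterError(f"pixel_um must be > 0, got {self.pixel_um}")
        if self.channel not in VALID_CHANNELS:
            raise ParameterError(
                f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """An ordered list of same-geometry frames (repeat frames or a Z-stack)."""

    frames: list[Image]
    z_step_um: Optional[float] = None
    alignment_offsets: Optional[list[tuple[float, float]]] = None  # (dy, dx) px

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ParameterError("stack must contain at least one frame")
        shape0, px0 = self.frames[0].shape, self.frames[0].pixel_um
        for f in self.frames[1:]:
            if f.shape != shape0 or f.pixel_um != px0:
                raise ParameterError("all frames must share shape and pixel_um")
        if self.alignment_offsets is not None and len(self.alignment_offsets) != len(
            self.frames
        ):
            raise ParameterError("alignment_offsets length must equal frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_um(self) -> float:
        return self.frames[0].pixel_um


@dataclass
class LineProfile:
    """Intensity samples along a line, equally spaced at ``step_um``."""

    positions_um: np.ndarray
    intensities: np.ndarray
    step_um: float
    source_line: tuple[tuple[float, float], tuple[float, float]]  # ((x1,y1),(x2,y2)) px
    averaging_width_px: int = 1

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions_um.shape != self.intensities.shape:
            raise ParameterError("positions and intensities must match in length")
        if len(self.positions_um) < 3:
            raise ParameterError("profile must have at least 3 samples")
        d = np.diff(self.positions_um)
        if not np.all(d > 0) or not np.allclose(d, self.step_um, rtol=1e-6, atol=1e-9):
            raise ParameterError("positions must increase uniformly at step_um")
        if np.any(self.intensities < 0):
            raise ParameterError("profile intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.positions_um)


@dataclass
class MinimaSet:
    """Local minima of a line profile with prominences and band labels.

    ``retained`` mirrors ``labels == 'iband'``: only I-band minima delimit
    sarcomeres; minima inside A-bands (M-lines) are excluded from length
    measurement.
    """

    positions_um: np.ndarray
    prominences: np.ndarray
    labels: np.ndarray  # of {'iband', 'aband_internal'}
    smoothed_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        self.prominences = np.asarray(self.prominences, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (
            len(self.positions_um) == len(self.prominences) == len(self.labels)
        ):
            raise ParameterError("minima arrays must share length")
        if len(self.positions_um) > 1 and not np.all(np.diff(self.positions_um) > 0):
            raise ParameterError("minima positions must be strictly increasing")

    @property
    def retained(self) -> np.ndarray:
        return np.asarray([lbl == LABEL_IBAND for lbl in self.labels], dtype=bool)

    @property
    def insufficient(self) -> bool:
        """True when fewer than two minima were found (no interval exists)."""
        return len(self.positions_um) < 2

    def __len__(self) -> int:
        return len(self.positions_um)


@dataclass
class SarcomereMeasurement:
    """Per-interval sarcomere lengths with summary statistics.

    ``n`` counts retained inter-minima intervals within the physiological
    bounds; out-of-bounds intervals are kept in ``flagged_lengths_um``.
    ``sd_um`` uses the n-1 denominator and is NaN for n < 2.
    """

    lengths_um: np.ndarray
    mean_um: float
    sd_um: float
    n: int
    band_regime_detected: str  # 'double' | 'single'
    flagged_lengths_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_minima_total: int = 0
    n_excluded_aband: int = 0
    failure_reason: Optional[str] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths_um = np.asarray(self.lengths_um, dtype=np.float64)
        self.flagged_lengths_um = np.asarray(self.flagged_lengths_um, dtype=np.float64)
        if self.n != len(self.lengths_um):
            raise ParameterError("n must equal len(lengths_um)")

    @property
    def ok(self) -> bool:
        return self.failure_reason is None


@dataclass
class InstanceMaskSet:
    """Integer instance label map plus per-label categories and geometry.

    ``label_map``: 0 = background, k > 0 = instance k. Every nonzero label
    must appear in ``categories`` and vice versa. ``fov_area_um2`` defaults
    to the full physical image area.
    """

    label_map: np.ndarray
    categories: dict[int, str]
    pixel_um: float
    fov_area_um2: Optional[float] = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 2:
            raise ParameterError("label_map must be 2D")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise ParameterError("label_map must be an integer array")
        if self.label_map.min() < 0:
            raise ParameterError("label_map values must be non-negative")
        if not (self.pixel_um > 0):
            raise ParameterError(f"pixel_um must be > 0, got {self.pixel_um}")
        present = set(np.unique(self.label_map).tolist()) - {0}
        declared = {int(k) for k in self.categories}
        if present != declared:
            raise ParameterError(
                "label map and category table disagree: "
                f"in map only {sorted(present - declared)}, "
                f"in table only {sorted(declared - present)}"
            )
        for k, cat in self.categories.items():
            if cat not in VALID_CATEGORIES:
                raise ParameterError(
                    f"label {k}: category must be one of {VALID_CATEGORIES}, got {cat!r}"
                )
        full = self.label_map.shape[0] * self.label_map.shape[1] * self.pixel_um**2
        if self.fov_area_um2 is None:
            self.fov_area_um2 = full
        labeled = int(np.count_nonzero(self.label_map)) * self.pixel_um**2
        if self.fov_area_um2 < labeled - 1e-6:
            raise ParameterError(
                f"fov_area_um2 ({self.fov_area_um2:.3g}) smaller than total "
                f"labeled area ({labeled:.3g})"
            )


@dataclass
class CapillarizationReport:
    """The three capillarization metrics for one ROI.

    cap_density_fov_um2  : capillary count / FOV area (um^-2)
    cap_density_cm_um2   : capillary count / total cardiomyocyte area (um^-2)
    cap_cm_ratio         : capillary count / cardiomyocyte count
    """

    n_cap: int
    n_cm: int
    cm_area_um2: float
    fov_area_um2: float
    cap_density_fov_um2: float
    cap_density_cm_um2: float
    cap_cm_ratio: float


@dataclass
class BinarizationSpec:
    """Binarization method selector.

    method      : 'global' (Otsu on a 256-bin histogram) or 'adaptive'
                  (local-mean threshold over a square window)
    window_px   : adaptive window side, odd and >= 3
    offset      : adaptive threshold = local mean - offset; negative values
                  demand intensities above the local mean (spot detection)
    """

    method: str = "global"
    window_px: int = 31
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("global", "adaptive"):
            raise ParameterError(f"method must be global|adaptive, got {self.method!r}")
        if self.method == "adaptive":
            if self.window_px < 3 or self.window_px % 2 == 0:
                raise ParameterError(
                    f"adaptive window_px must be odd and >= 3, got {self.window_px}"
                )
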