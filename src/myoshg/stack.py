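"""Raw-image processing: frame averaging, filtering, drift correction,
binarization.

The stage order mirrors the acquisition pipeline: frame averaging ->
Gaussian or Wiener filtering -> translational drift correction of
Z-stacks -> global or adaptive binarization. Drift correction uses
phase-correlation translational registration with sub-pixel (upsampled)
refinement. Boundary handling is reflect everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu
from skimage.registration import phase_cross_correlation

from .datatypes import BinarizationSpec, Image, ImageStack
from .exceptions import ParameterError


def average_frames(stack: ImageStack) -> Image:
    """Pixel-wise arithmetic mean of all frames, in float64.

    For Poisson-noise-limited frames the SNR improves as sqrt(N).
    """
    arr = np.stack([f.pixels for f in stack.frames])
    return Image(
        pixels=arr.mean(axis=0),
        pixel_um=stack.pixel_um,
        channel=stack.frames[0].channel,
    )


def filter_gaussian(image: Image, sigma_um: float) -> Image:
    """Separable Gaussian smoothing (SD in um, reflect boundary).

    ``sigma_um = 0`` is the identity.
    """
    if sigma_um < 0:
        raise ParameterError(f"sigma_um must be >= 0, got {sigma_um}")
    if sigma_um == 0:
        return Image(image.pixels.copy(), image.pixel_um, image.channel)
    out = ndimage.gaussian_filter(
        image.pixels, sigma_um / image.pixel_um, mode="reflect"
    )
    return Image(np.clip(out, 0, None), image.pixel_um, image.channel)


def filter_wiener(
    image: Image, window_px: int = 5, noise_power: float | None = None
) -> Image:
    """Local-statistics (lee) adaptive Wiener filter.

    Local mean m and variance v are estimated over a ``window_px`` square
    (reflect boundary); the output is ``m + max(v - n, 0)/v * (x - m)``
    with noise power ``n`` auto-estimated as the median of local variances
    when not supplied. A noiseless constant image passes through
    unchanged.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ParameterError(f"window_px must be odd and >= 3, got {window_px}")
    x = image.pixels
    m = ndimage.uniform_filter(x, window_px, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, window_px, mode="reflect")
    v = np.clip(m2 - m * m, 0, None)
    n = float(np.median(v)) if noise_power is None else float(noise_power)
    if n < 0:
        raise ParameterError(f"noise_power must be >= 0, got {noise_power}")
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(v > 0, np.clip((v - n) / np.where(v > 0, v, 1), 0, 1), 0.0)
    out = m + gain * (x - m)
    return Image(np.clip(out, 0, None), image.pixel_um, image.channel)


@dataclass
class AlignmentResult:
    """Aligned stack plus per-frame applied shifts and confidence flags."""

    stack: ImageStack
    offsets: list[tuple[float, float]]  # (dy, dx) px applied to each frame
    low_confidence: list[bool] = field(default_factory=list)


def align_stack(
    stack: ImageStack,
    reference: str = "first",
    upsample_factor: int = 50,
) -> AlignmentResult:
    """Correct translational drift by phase correlation.

    Per-frame (dy, dx) shifts are estimated against the first frame
    (``reference='first'``) or composed from consecutive-frame estimates
    (``'previous'``), refined to sub-pixel precision by local Fourier
    upsampling, and applied by bilinear shifting with reflect padding.
    Frames are mean-subtracted and Hann-windowed before correlation to
    suppress the wrap-around edge bias of FFT correlation on non-periodic
    fields. A constant frame gets offset (0, 0) and a low-confidence flag.

    Purely one-dimensional patterns (an untextured striation lattice)
    constrain only the shift component along their axis; recovery of both
    components needs two-dimensional structure.
    """
    if reference not in ("first", "previous"):
        raise ParameterError(f"reference must be first|previous, got {reference!r}")
    if len(stack) < 2:
        raise ParameterError("alignment needs at least 2 frames")
    shape = stack.frames[0].shape
    hann = np.hanning(shape[0])[:, None] * np.hanning(shape[1])[None, :]
    frames = [f.pixels for f in stack.frames]
    windowed = [(p - p.mean()) * hann for p in frames]
    n = len(frames)
    offsets = [(0.0, 0.0)]
    low_conf = [bool(np.ptp(frames[0]) == 0)]
    for i in range(1, n):
        if np.ptp(frames[i]) == 0:
            offsets.append((0.0, 0.0))
            low_conf.append(True)
            continue
        j = 0 if reference == "first" else i - 1
        if np.ptp(frames[j]) == 0:
            offsets.append(offsets[-1] if reference == "previous" else (0.0, 0.0))
            low_conf.append(True)
            continue
        shift, _, _ = phase_cross_correlation(
            windowed[j],
            windowed[i],
            upsample_factor=upsample_factor,
            normalization=None,
        )
        dy, dx = float(shift[0]), float(shift[1])
        if reference == "previous":
            pdy, pdx = offsets[i - 1]
            dy, dx = dy + pdy, dx + pdx
        offsets.append((dy, dx))
        low_conf.append(False)
    aligned = []
    for f, (dy, dx) in zip(stack.frames, offsets):
        shifted = ndimage.shift(f.pixels, (dy, dx), order=1, mode="reflect")
        aligned.append(Image(np.clip(shifted, 0, None), f.pixel_um, f.channel))
    new_stack = ImageStack(
        frames=aligned, z_step_um=stack.z_step_um, alignment_offsets=offsets
    )
    return AlignmentResult(stack=new_stack, offsets=offsets, low_confidence=low_conf)


def binarize(image: Image, spec: BinarizationSpec) -> tuple[np.ndarray, dict]:
    """Threshold an image to a {0, 1} mask.

    global   : Otsu threshold on a 256-bin histogram over the data range
    adaptive : pixel > local mean (square ``window_px``) - ``offset``

    Returns ``(mask_uint8, info)`` where ``info`` records the method and
    threshold(s); a constant image yields an all-background mask with
    ``info['constant_input'] = True`` instead of an error.
    """
    x = image.pixels
    info: dict = {"method": spec.method, "constant_input": False}
    if np.ptp(x) == 0:
        info["constant_input"] = True
        info["threshold"] = None
        return np.zeros_like(x, dtype=np.uint8), info
    if spec.method == "global":
        thr = float(threshold_otsu(x, nbins=256))
        info["threshold"] = thr
        mask = x > thr
    else:
        local = threshold_local(
            x,
            block_size=spec.window_px,
            method="mean",
            offset=spec.offset,
            mode="reflect",
        )
        info["window_px"] = spec.window_px
        info["offset"] = spec.offset
        info["threshold_mean"] = float(np.mean(local))
        mask = x > local
    return mask.astype(np.uint8), info


def preprocess_chain(
    stack: ImageStack,
    average: bool = False,
    gaussian_sigma_um: float | None = None,
    wiener_window_px: int | None = None,
    align_reference: str | None = None,
    binarization: BinarizationSpec | None = None,
) -> dict:
    """Run the fixed-order chain: average -> filter -> align -> binarize.

    Stages are optional; averaging collapses the stack to a single frame,
    which is incompatible with a subsequent alignment request. Returns a
    dict with the surviving ``stack``/``image``, ``offsets``, ``masks``
    and stage provenance.
    """
    out: dict = {"stages": []}
    if average and align_reference:
        raise ParameterError(
            "averaging collapses the stack; it cannot precede alignment"
        )
    if average:
        stack = ImageStack(frames=[average_frames(stack)], z_step_um=None)
        out["stages"].append("average")
    if gaussian_sigma_um is not None and wiener_window_px is not None:
        raise ParameterError("choose either Gaussian or Wiener filtering, not both")
    if gaussian_sigma_um is not None:
        stack = replace(
            stack,
            frames=[filter_gaussian(f, gaussian_sigma_um) for f in stack.frames],
        )
        out["stages"].append("gaussian")
    if wiener_window_px is not None:
        stack = replace(
            stack,
            frames=[filter_wiener(f, wiener_window_px) for f in stack.frames],
        )
        out["stages"].append("wiener")
    if align_reference:
        res = align_stack(stack, reference=align_reference)
        stack = res.stack
        out["offsets"] = res.offsets
        out["low_confidence"] = res.low_confidence
        out["stages"].append("align")
    out["stack"] = stack
    if binarization is not None:
        masks, infos = [], []
        for f in stack.frames:
            m, info = binarize(f, binarization)
            masks.append(m)
            infos.append(info)
        out["masks"] = masks
        out["binarization"] = infos
        out["stages"].append("binarize")
    return out
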