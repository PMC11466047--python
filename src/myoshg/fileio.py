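"""TIFF/CSV/JSON input and output.

Images travel as single- or multi-page grayscale 8/16-bit TIFF with the
pixel size stored in the resolution tags (pixels per centimetre); an
explicit ``pixel_um`` argument always overrides the tags. Instance masks
are 16-bit label TIFFs with a sidecar category CSV (columns:
``label,category``). Reports are deterministic JSON (sorted keys, no
timestamps) plus CSV tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import VALID_CATEGORIES, Image, ImageStack, InstanceMaskSet
from .exceptions import FormatError, ParameterError

_ALLOWED_DTYPES = (np.uint8, np.uint16)


def _pixel_um_from_tags(page: "tifffile.TiffPage") -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = int(tags["ResolutionUnit"].value)
    per_um = {2: num / den / 25400.0, 3: num / den / 10000.0}.get(unit)
    if per_um is None or per_um <= 0:
        return None
    return 1.0 / per_um


def _load_pages(path: str | Path) -> tuple[list[np.ndarray], Optional[float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = tifffile.TiffFile(path)
    except tifffile.TiffFileError as exc:
        raise FormatError(f"{path}: not a readable TIFF file ({exc})") from exc
    with tf:
        arrays = []
        tag_px = _pixel_um_from_tags(tf.pages[0])
        for page in tf.pages:
            arr = page.asarray()
            if arr.ndim != 2:
                raise FormatError(
                    f"{path}: unsupported pixel layout with shape {arr.shape}; "
                    "expected single-channel grayscale"
                )
            if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
                raise FormatError(
                    f"{path}: unsupported pixel type {arr.dtype}; "
                    "expected 8- or 16-bit unsigned grayscale"
                )
            arrays.append(arr)
    return arrays, tag_px


def _resolve_pixel_um(
    explicit: Optional[float], from_tags: Optional[float], path: str | Path
) -> float:
    if explicit is not None:
        if explicit <= 0:
            raise ParameterError(f"pixel_um must be > 0, got {explicit}")
        return explicit
    if from_tags is not None:
        return from_tags
    raise ParameterError(
        f"{path}: no resolution metadata in TIFF; pass pixel_um explicitly "
        "(CLI flag --pixel-um)"
    )


def read_image(
    path: str | Path, pixel_um: Optional[float] = None, channel: str = "F-SHG"
) -> Image:
    """Read the first page of a grayscale 8/16-bit TIFF, bit-exactly."""
    arrays, tag_px = _load_pages(path)
    return Image(
        pixels=arrays[0].astype(np.float64),
        pixel_um=_resolve_pixel_um(pixel_um, tag_px, path),
        channel=channel,
    )


def read_stack(
    path: str | Path,
    pixel_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
    channel: str = "F-SHG",
) -> ImageStack:
    """Read a multi-page TIFF as a stack, pages in file order."""
    arrays, tag_px = _load_pages(path)
    px = _resolve_pixel_um(pixel_um, tag_px, path)
    frames = [
        Image(pixels=a.astype(np.float64), pixel_um=px, channel=channel)
        for a in arrays
    ]
    return ImageStack(frames=frames, z_step_um=z_step_um)


def _resolution_kwargs(pixel_um: float) -> dict:
    ppcm = 1e4 / pixel_um
    return {
        "resolution": (ppcm, ppcm),
        "resolutionunit": "CENTIMETER",
        "photometric": "minisblack",
    }


def write_image(path: str | Path, image: Image) -> None:
    """Write an image as single-page 16-bit grayscale TIFF.

    Intensities are rounded to integers; values above 65535 are an error
    (no silent clipping).
    """
    arr = np.round(image.pixels)
    if arr.max() > 65535:
        raise ParameterError(
            f"intensity {arr.max():.0f} exceeds the 16-bit range; rescale first"
        )
    tifffile.imwrite(
        path, arr.astype(np.uint16), **_resolution_kwargs(image.pixel_um)
    )


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page 16-bit grayscale TIFF."""
    arr = np.round(np.stack([f.pixels for f in stack.frames]))
    if arr.max() > 65535:
        raise ParameterError(
            f"intensity {arr.max():.0f} exceeds the 16-bit range; rescale first"
        )
    tifffile.imwrite(
        path, arr.astype(np.uint16), **_resolution_kwargs(stack.pixel_um)
    )


def write_mask_set(
    mask_path: str | Path, categories_path: str | Path, masks: InstanceMaskSet
) -> None:
    """Write a label TIFF plus the sidecar category CSV."""
    if masks.label_map.max() > 65535:
        raise ParameterError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(
        mask_path,
        masks.label_map.astype(np.uint16),
        **_resolution_kwargs(masks.pixel_um),
    )
    pd.DataFrame(
        sorted(masks.categories.items()), columns=["label", "category"]
    ).to_csv(categories_path, index=False)


def read_mask_set(
    mask_path: str | Path,
    categories_path: str | Path,
    pixel_um: Optional[float] = None,
    fov_area_um2: Optional[float] = None,
) -> InstanceMaskSet:
    """Read a label TIFF and its category CSV into an InstanceMaskSet."""
    arrays, tag_px = _load_pages(mask_path)
    px = _resolve_pixel_um(pixel_um, tag_px, mask_path)
    table = pd.read_csv(categories_path)
    if not {"label", "category"} <= set(table.columns):
        raise FormatError(
            f"{categories_path}: category CSV needs columns label,category"
        )
    categories = {}
    for _, row in table.iterrows():
        cat = str(row["category"]).strip()
        if cat not in VALID_CATEGORIES:
            raise FormatError(
                f"{categories_path}: unknown category {cat!r} "
                f"(expected one of {VALID_CATEGORIES})"
            )
        categories[int(row["label"])] = cat
    return InstanceMaskSet(
        label_map=arrays[0].astype(np.int64),
        categories=categories,
        pixel_um=px,
        fov_area_um2=fov_area_um2,
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_safe(obj):
    """Recursively convert to JSON types; NaN becomes null."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    return obj


def write_report(
    summary: dict,
    json_path: str | Path,
    tables: Optional[dict[str, pd.DataFrame]] = None,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    input_paths: Optional[list[str | Path]] = None,
) -> None:
    """Write a deterministic JSON summary plus optional CSV tables.

    The JSON carries the tool version, the full configuration, the seed
    and sha256 checksums of the inputs; keys are sorted and no timestamp
    is included, so identical inputs yield byte-identical files. Each
    table ``name`` is written next to the JSON as ``<stem>_<name>.csv``.
    """
    from . import __version__

    json_path = Path(json_path)
    doc = {
        "tool": "myoshg",
        "version": __version__,
        "seed": seed,
        "config": _json_safe(config or {}),
        "inputs": {
            str(p): sha256_of(p) for p in (input_paths or []) if Path(p).exists()
        },
        "results": _json_safe(summary),
    }
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")
    for name, table in (tables or {}).items():
        table.to_csv(
            json_path.with_name(f"{json_path.stem}_{name}.csv"), index=False
        )
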