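"""Capillarization metrics from categorized instance masks.

Three measurements per ROI, computed from an instance label map whose
labels carry a category (cardiomyocyte or capillary):

1. capillary density normalized to FOV: capillary count / FOV area (um^-2)
2. capillary density normalized to cardiomyocyte area: capillary count /
   total cardiomyocyte mask area (um^-2)
3. capillary-to-cardiomyocyte ratio: capillary count / cardiomyocyte count

Counts are label-based (instances), never pixel-based: splitting one
capillary into two labels raises the count by one regardless of area.
Labels touching the image border are counted by default; pass
``exclude_border=True`` to drop them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CATEGORY_CAPILLARY,
    CATEGORY_CARDIOMYOCYTE,
    CapillarizationReport,
    InstanceMaskSet,
)
from .exceptions import ParameterError, UndefinedMetricError

METRIC_COLUMNS = ("cap_density_fov_um2", "cap_density_cm_um2", "cap_cm_ratio")


def _border_labels(label_map: np.ndarray) -> set[int]:
    edges = np.concatenate(
        [label_map[0, :], label_map[-1, :], label_map[:, 0], label_map[:, -1]]
    )
    return set(np.unique(edges).tolist()) - {0}


def _counts_and_areas(
    masks: InstanceMaskSet, exclude_border: bool = False
) -> tuple[int, int, float]:
    """(n_cap, n_cm, cm_area_um2) for one mask set."""
    drop = _border_labels(masks.label_map) if exclude_border else set()
    n_cap = sum(
        1
        for k, c in masks.categories.items()
        if c == CATEGORY_CAPILLARY and k not in drop
    )
    n_cm = 0
    cm_area_px = 0
    labels, counts = np.unique(masks.label_map, return_counts=True)
    area_px = dict(zip(labels.tolist(), counts.tolist()))
    for k, c in masks.categories.items():
        if c == CATEGORY_CARDIOMYOCYTE and k not in drop:
            n_cm += 1
            cm_area_px += area_px.get(k, 0)
    return n_cap, n_cm, cm_area_px * masks.pixel_um**2


def capillary_density_fov(
    masks: InstanceMaskSet, exclude_border: bool = False
) -> float:
    """Capillary count divided by FOV area (um^-2)."""
    if not (masks.fov_area_um2 and masks.fov_area_um2 > 0):
        raise ParameterError(f"fov_area_um2 must be > 0, got {masks.fov_area_um2}")
    n_cap, _, _ = _counts_and_areas(masks, exclude_border)
    return n_cap / masks.fov_area_um2


def capillary_density_cm_area(
    masks: InstanceMaskSet, exclude_border: bool = False
) -> float:
    """Capillary count divided by total cardiomyocyte mask area (um^-2).

    Raises :class:`UndefinedMetricError` when the cardiomyocyte area is
    zero: the quotient is undefined, not 0 and not infinity.
    """
    n_cap, _, cm_area = _counts_and_areas(masks, exclude_border)
    if cm_area <= 0:
        raise UndefinedMetricError(
            "capillary density per cardiomyocyte area undefined: "
            "zero cardiomyocyte area"
        )
    return n_cap / cm_area


def capillary_cm_ratio(masks: InstanceMaskSet, exclude_border: bool = False) -> float:
    """Capillary count divided by cardiomyocyte count (dimensionless)."""
    n_cap, n_cm, _ = _counts_and_areas(masks, exclude_border)
    if n_cm == 0:
        raise UndefinedMetricError(
            "capillary-to-cardiomyocyte ratio undefined: no cardiomyocytes"
        )
    return n_cap / n_cm


def capillarization_report(
    masks: InstanceMaskSet, exclude_border: bool = False
) -> CapillarizationReport:
    """All three metrics for one ROI."""
    n_cap, n_cm, cm_area = _counts_and_areas(masks, exclude_border)
    if n_cm == 0 or cm_area <= 0:
        raise UndefinedMetricError(
            "capillarization report undefined: no cardiomyocytes in ROI"
        )
    assert masks.fov_area_um2 is not None
    return CapillarizationReport(
        n_cap=n_cap,
        n_cm=n_cm,
        cm_area_um2=cm_area,
        fov_area_um2=masks.fov_area_um2,
        cap_density_fov_um2=n_cap / masks.fov_area_um2,
        cap_density_cm_um2=n_cap / cm_area,
        cap_cm_ratio=n_cap / n_cm,
    )


@dataclass
class RoiSummary:
    """Per-ROI metric table plus cross-ROI mean/SD (n-1 denominator).

    ``per_roi`` has one row per ROI (columns: roi, n_cap, n_cm,
    cm_area_um2, fov_area_um2, the three metrics, flag). ROIs where a
    metric is undefined are flagged with the reason, excluded from the
    summary, and never abort the whole report. ``summary`` maps metric ->
    {'mean', 'sd', 'n'}.
    """

    per_roi: pd.DataFrame
    summary: dict[str, dict[str, float]]


def summarize_rois(
    mask_sets: list[InstanceMaskSet], exclude_border: bool = False
) -> RoiSummary:
    """Compute the three metrics per ROI and the cross-ROI mean +- SD."""
    rows = []
    for i, masks in enumerate(mask_sets):
        row: dict = {"roi": i, "flag": ""}
        try:
            rep = capillarization_report(masks, exclude_border)
            row.update(
                n_cap=rep.n_cap,
                n_cm=rep.n_cm,
                cm_area_um2=rep.cm_area_um2,
                fov_area_um2=rep.fov_area_um2,
                cap_density_fov_um2=rep.cap_density_fov_um2,
                cap_density_cm_um2=rep.cap_density_cm_um2,
                cap_cm_ratio=rep.cap_cm_ratio,
            )
        except UndefinedMetricError as exc:
            n_cap, n_cm, cm_area = _counts_and_areas(masks, exclude_border)
            row.update(
                n_cap=n_cap,
                n_cm=n_cm,
                cm_area_um2=cm_area,
                fov_area_um2=masks.fov_area_um2,
                cap_density_fov_um2=np.nan,
                cap_density_cm_um2=np.nan,
                cap_cm_ratio=np.nan,
                flag=str(exc),
            )
        rows.append(row)
    per_roi = pd.DataFrame(rows)
    summary: dict[str, dict[str, float]] = {}
    for col in METRIC_COLUMNS:
        vals = per_roi.loc[per_roi["flag"] == "", col].to_numpy(dtype=float)
        summary[col] = {
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan"),
            "n": int(len(vals)),
        }
    return RoiSummary(per_roi=per_roi, summary=summary)


def categorize_by_area(
    label_map: np.ndarray, pixel_um: float, capillary_max_area_um2: float
) -> dict[int, str]:
    """Heuristic size-based categorization (explicit opt-in only).

    Labels with area <= ``capillary_max_area_um2`` become capillaries,
    larger ones cardiomyocytes. Intended for mask sources that do not
    attach categories; the category table remains the primary contract.
    """
    labels, counts = np.unique(label_map, return_counts=True)
    out: dict[int, str] = {}
    for k, c in zip(labels.tolist(), counts.tolist()):
        if k == 0:
            continue
        area = c * pixel_um**2
        out[k] = (
            CATEGORY_CAPILLARY
            if area <= capillary_max_area_um2
            else CATEGORY_CARDIOMYOCYTE
        )
    return out
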