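"""ROI-based image-quality metrics: contrast enhancement, CNR, and iodine
concentration error.

ROIs are squares centred in each peripheral insert; the background ROI is
the same-size square in the central water insert.  CNR follows the
detectability definition 2 |mean_roi - mean_bg| / sqrt(var_roi + var_bg),
with CNR ~ 2 the conventional visibility threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import DigitalPhantom

__all__ = [
    "RoiSpec",
    "default_rois",
    "contrast_enhancement",
    "cnr",
    "concentration_error",
]


@dataclass(frozen=True)
class RoiSpec:
    """Square pixel ROIs for the inserts plus the central background.

    ``insert_rois`` holds one ``(row, col, side)`` triple per peripheral
    insert (ROI spans ``side`` pixels centred at row/col); ``background``
    is the same triple inside the central water insert.
    """

    insert_rois: tuple[tuple[int, int, int], ...]
    background: tuple[int, int, int]

    def insert_mask(self, index: int, shape: tuple[int, int]) -> np.ndarray:
        return _square_mask(self.insert_rois[index], shape)

    def background_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return _square_mask(self.background, shape)


def _square_mask(roi: tuple[int, int, int], shape) -> np.ndarray:
    r, c, side = roi
    m = np.zeros(shape, dtype=bool)
    half = side // 2
    r0, c0 = r - half, c - half
    if r0 < 0 or c0 < 0 or r0 + side > shape[0] or c0 + side > shape[1]:
        raise ValueError(f"ROI {roi} falls outside the image {shape}")
    m[r0 : r0 + side, c0 : c0 + side] = True
    return m


def default_rois(
    phantom: DigitalPhantom, side: int | None = None, margin_px: int = 2
) -> RoiSpec:
    """Square ROIs centred in each insert, strictly inside with a margin.

    ``side`` defaults to 10 pixels when that fits inside the insert circle
    with the requested margin, otherwise to the largest square that does.
    """
    h = phantom.pixel_size
    r_px = phantom.insert_radius_cm / h
    max_side = int(math.floor((r_px - margin_px) * math.sqrt(2.0)))
    if max_side < 2:
        raise ValueError("inserts too small for a valid ROI at this grid")
    if side is None:
        side = min(10, max_side)
    elif side > max_side:
        raise ValueError(
            f"ROI side {side} px does not fit inside the insert "
            f"(max {max_side} at margin {margin_px})"
        )
    ny, nx = phantom.shape
    rois = []
    for cx, cy in phantom.insert_centers_cm[1:]:
        col = int(round(cx / h + (nx - 1) / 2.0))
        row = int(round(cy / h + (ny - 1) / 2.0))
        rois.append((row, col, side))
    bg = (int(round((ny - 1) / 2.0)), int(round((nx - 1) / 2.0)), side)
    return RoiSpec(insert_rois=tuple(rois), background=bg)


def contrast_enhancement(
    image: np.ndarray, roi_mask: np.ndarray, bg_mask: np.ndarray
) -> float:
    """Signed mean(ROI) - mean(background)."""
    if not roi_mask.any() or not bg_mask.any():
        raise ValueError("empty ROI mask")
    return float(image[roi_mask].mean() - image[bg_mask].mean())


def cnr(image: np.ndarray, roi_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio 2 |d| / sqrt(var_roi + var_bg) (magnitude).

    Returns inf (with a warning) when both regions have zero variance but a
    nonzero mean difference.
    """
    if roi_mask.sum() < 4 or bg_mask.sum() < 4:
        raise ValueError("each ROI needs at least 4 pixels")
    roi, bg = image[roi_mask], image[bg_mask]
    d = float(roi.mean() - bg.mean())
    v = float(roi.var(ddof=1) + bg.var(ddof=1))
    if v == 0.0:
        if d == 0.0:
            return 0.0
        warnings.warn("zero variance with nonzero contrast: CNR is infinite")
        return math.inf
    return 2.0 * abs(d) / math.sqrt(v)


def concentration_error(
    estimate_map: np.ndarray,
    truth_mg_per_ml: np.ndarray,
    rois: RoiSpec,
) -> tuple[np.ndarray, float, list[int]]:
    """Per-insert relative iodine-concentration errors and their mean.

    ``estimate_map`` is the reconstructed iodine density image (mg/ml);
    ``truth_mg_per_ml`` the ground-truth insert values in ROI order.
    Zero-truth inserts are excluded (their indices are returned).  Returns
    ``(per_insert_errors, mean_error, excluded_indices)`` where excluded
    entries hold NaN.
    """
    truth = np.asarray(truth_mg_per_ml, dtype=float)
    if len(truth) != len(rois.insert_rois):
        raise ValueError("truth length must match the insert ROI count")
    errs = np.full(len(truth), np.nan)
    excluded = []
    for i, t in enumerate(truth):
        if t <= 0:
            excluded.append(i)
            continue
        est = float(estimate_map[rois.insert_mask(i, estimate_map.shape)].mean())
        errs[i] = abs(est - t) / t
    if excluded:
        warnings.warn(f"inserts {excluded} have zero truth and were excluded")
    valid = ~np.isnan(errs)
    if not valid.any():
        raise ValueError("no insert with positive ground-truth concentration")
    return errs, float(errs[valid].mean()), excluded
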