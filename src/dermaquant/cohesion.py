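"""Non-cohesive (expanded intercellular) space quantification.

HES-like composites are converted to grayscale, thresholded against a
tissue-free background estimate, and pixels darker than the threshold
inside the epidermis are marked as intercellular space ("red pixels" in
the QC overlay).  The score is expressed per epidermis area:
``score_au = 100 * space_px / epidermis_px``, so sections of different
lengths are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DermaquantError, ValidationError

#: Rec. 601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class CohesionResult:
    space_mask: np.ndarray
    space_px: int
    epidermis_px: int

    @property
    def score_au(self) -> float:
        return 100.0 * self.space_px / self.epidermis_px


def grayscale(hes_rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB composite, range-preserving.

    Returns uint8 for uint8 input (rounded), float otherwise.
    """
    hes_rgb = np.asarray(hes_rgb)
    if hes_rgb.ndim != 3 or hes_rgb.shape[2] != 3:
        raise ValidationError("hes_rgb: expected an H x W x 3 raster")
    lum = hes_rgb.astype(float) @ _LUMA
    if hes_rgb.dtype == np.uint8:
        return np.clip(np.round(lum), 0, 255).astype(np.uint8)
    return lum


def space_mask(
    gray: np.ndarray,
    epidermis_mask: np.ndarray,
    threshold: float,
    min_object_px: int = 20,
    invert: bool = False,
) -> CohesionResult:
    """Mark intercellular spaces inside the epidermis.

    Pixels at or below ``threshold`` (at or above, with ``invert=True`` for
    bright-space imagery) within the epidermis mask are space; connected
    components smaller than ``min_object_px`` are dropped as noise.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.shape != epidermis_mask.shape:
        raise ValidationError("epidermis_mask: shape mismatch with gray raster")
    epi_px = int(epidermis_mask.sum())
    if epi_px == 0:
        raise DermaquantError("no epidermis: the epidermis mask is empty")
    dark = gray >= threshold if invert else gray <= threshold
    mask = dark & epidermis_mask
    if min_object_px > 1 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes >= min_object_px
        mask = keep[labels]
    return CohesionResult(space_mask=mask, space_px=int(mask.sum()), epidermis_px=epi_px)


def overlay_rgb(gray: np.ndarray, result: CohesionResult) -> np.ndarray:
    """QC overlay: grayscale base with detected spaces painted red."""
    g = np.asarray(gray, dtype=float)
    if g.max() > 0:
        g = g / g.max() * 255.0
    rgb = np.stack([g, g, g], axis=-1)
    rgb[result.space_mask] = (255.0, 0.0, 0.0)
    return rgb.astype(np.uint8)


def cohesion_by_region(
    gray: np.ndarray,
    epidermis_mask: np.ndarray,
    regions_um: list[tuple[float, float]],
    threshold: float,
    pixel_size_um: float,
    min_object_px: int = 20,
    invert: bool = False,
) -> pd.DataFrame:
    """Per-region cohesion scores over intervals along the section axis.

    The space mask is computed once on the whole epidermis (so noise
    filtering cannot depend on where region boundaries fall, and pixel
    counts of a partition sum exactly to the whole-section counts) and then
    counted per (start_um, end_um) column interval.  A region whose
    epidermis sub-mask is empty gets a null score and ``flagged=True``.
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um: must be positive")
    whole = space_mask(gray, epidermis_mask, threshold, min_object_px=min_object_px, invert=invert)
    w = epidermis_mask.shape[1]
    cols_um = (np.arange(w) + 0.5) * pixel_size_um
    length = w * pixel_size_um
    rows = []
    for i, (a, b) in enumerate(regions_um):
        if not (0 <= a < b <= length + 1e-9):
            raise ValidationError(f"regions_um: interval ({a}, {b}) outside [0, {length}]")
        colmask = (cols_um >= a) & (cols_um < b)
        epi_px = int((epidermis_mask & colmask[None, :]).sum())
        if epi_px == 0:
            rows.append(dict(region=i, start_um=a, end_um=b, space_px=0, epidermis_px=0, score_au=np.nan, flagged=True))
            continue
        sp = int((whole.space_mask & colmask[None, :]).sum())
        rows.append(
            dict(region=i, start_um=a, end_um=b, space_px=sp, epidermis_px=epi_px, score_au=100.0 * sp / epi_px, flagged=False)
        )
    return pd.DataFrame(rows)
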