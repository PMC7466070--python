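"""Semi-quantitative immunofluorescence: masked marker levels with optional
DAPI normalization, and positive-cell percentages for nuclear markers.

Levels are arbitrary units (a.u.): background-subtracted intensity sums
over a mask, optionally divided by the DAPI sum over the same mask so that
acquisition gain cancels.  Positivity of a nucleus is decided by its mean
marker intensity against a threshold derived from a known-negative
compartment (mean + 3 SD of per-nucleus means), the automated surrogate
for manual positive-cell counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DermaquantError, ValidationError
from .polarity import NucleusRecord


@dataclass
class MarkerLevel:
    marker: str
    mask_kind: str  # basal_band / epidermis / custom
    total_signal: float
    normalizer: str  # none / dapi
    level_au: float


@dataclass
class PositiveCellResult:
    marker: str
    n_cells: int
    n_positive: int
    positivity_threshold: float
    flagged: bool = False

    @property
    def percent_positive(self) -> float | None:
        if self.n_cells == 0:
            return None
        return 100.0 * self.n_positive / self.n_cells


def marker_level(
    marker: np.ndarray,
    mask: np.ndarray,
    dapi: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
    marker_name: str = "marker",
    mask_kind: str = "custom",
) -> MarkerLevel:
    """Background-subtracted marker level over a mask.

    The background is the median marker intensity outside the tissue
    (``background_mask``; zero when not given).  With ``dapi`` supplied the
    level is normalized as sum(marker) / sum(dapi) over the same mask,
    which is invariant to a common acquisition gain.
    """
    marker = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if marker.shape != mask.shape:
        raise ValidationError("mask: shape mismatch with marker raster")
    if not mask.any():
        raise ValidationError("mask: empty mask")
    bg = float(np.median(marker[background_mask])) if background_mask is not None and background_mask.any() else 0.0
    signal = marker[mask] - bg
    total = float(np.clip(signal, 0.0, None).sum())
    if dapi is None:
        return MarkerLevel(marker=marker_name, mask_kind=mask_kind, total_signal=total, normalizer="none", level_au=total)
    dapi = np.asarray(dapi, dtype=float)
    if dapi.shape != mask.shape:
        raise ValidationError("dapi: shape mismatch with mask")
    dapi_bg = float(np.median(dapi[background_mask])) if background_mask is not None and background_mask.any() else 0.0
    total_dapi = float(np.clip(dapi[mask] - dapi_bg, 0.0, None).sum())
    if total_dapi == 0:
        raise DermaquantError("degenerate normalizer: DAPI sums to zero within the mask")
    return MarkerLevel(marker=marker_name, mask_kind=mask_kind, total_signal=total, normalizer="dapi", level_au=total / total_dapi)


def _per_nucleus_means(marker: np.ndarray, label_map: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return ndimage.mean(marker, labels=label_map, index=labels)


def positivity_threshold(marker: np.ndarray, label_map: np.ndarray, negative_labels: list[int], k: float = 3.0) -> float:
    """Positivity cutoff from a known-negative nucleus population.

    Threshold = mean + k * SD of the per-nucleus mean intensities of the
    negative nuclei (mirroring a no-primary-antibody negative control).
    """
    if len(negative_labels) == 0:
        raise ValidationError("negative_labels: at least one negative nucleus required")
    means = _per_nucleus_means(np.asarray(marker, dtype=float), label_map, np.asarray(negative_labels))
    return float(np.mean(means) + k * np.std(means))


def positive_cells(
    marker: np.ndarray,
    nuclei: list[NucleusRecord],
    label_map: np.ndarray,
    threshold: float,
    compartments: set[str] | None = None,
    marker_name: str = "marker",
) -> PositiveCellResult:
    """Count marker-positive nuclei among the requested compartments.

    A nucleus is positive iff the mean marker intensity over its labeled
    pixels exceeds ``threshold``.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape != label_map.shape:
        raise ValidationError("label_map: shape mismatch with marker raster")
    sel = [n for n in nuclei if compartments is None or n.compartment in compartments]
    if not sel:
        return PositiveCellResult(marker=marker_name, n_cells=0, n_positive=0, positivity_threshold=float(threshold), flagged=True)
    labels = np.asarray([n.label for n in sel])
    means = _per_nucleus_means(marker, label_map, labels)
    n_pos = int(np.sum(means > threshold))
    return PositiveCellResult(marker=marker_name, n_cells=len(sel), n_positive=n_pos, positivity_threshold=float(threshold))
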