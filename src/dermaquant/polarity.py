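"""Basal-keratinocyte polarity: nucleus segmentation, orientation relative
to the dermo-epidermal junction, 18-category angle histograms and the
three-class polarity summary (nearly perpendicular / oblique / nearly
parallel).

In healthy stratified epidermis, basal nuclei sit with their long axis
perpendicular to the junction; a shift of the angle distribution toward
oblique and parallel orientations is the quantitative signature of a loss
of epithelial polarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import ValidationError
from .geometry import acute_angle_between
from .masks import CompartmentMasks, JdePolyline

#: histogram layout: 18 five-degree categories over [0, 90]
BIN_EDGES = np.arange(0.0, 91.0, 5.0)

#: class boundaries in degrees; angles >= PERPENDICULAR_MIN are "nearly
#: perpendicular", angles < PARALLEL_MAX are "nearly parallel"
PARALLEL_MAX = 30.0
PERPENDICULAR_MIN = 60.0

LOW_ECCENTRICITY = 0.05


class PolarityClass(str, Enum):
    NEARLY_PERPENDICULAR = "nearly_perpendicular"
    OBLIQUE = "oblique"
    NEARLY_PARALLEL = "nearly_parallel"


@dataclass
class NucleusRecord:
    """One segmented nucleus with its equivalent-ellipse orientation."""

    label: int
    centroid_x: float
    centroid_y: float
    area_px: int
    major_axis_angle_deg: float  # from +x axis, in [0, 180)
    eccentricity: float
    compartment: str  # basal / suprabasal / dermis / background
    low_confidence: bool = False


@dataclass
class AngleHistogram:
    """Counts of nuclei in the 18 five-degree angle categories."""

    counts: np.ndarray
    n: int
    bin_edges: np.ndarray = None

    def __post_init__(self) -> None:
        if self.bin_edges is None:
            self.bin_edges = BIN_EDGES.copy()
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != 18 or int(self.counts.sum()) != self.n:
            raise ValidationError("counts: need 18 bins summing to n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:], "count": self.counts}
        )


def _label_moments(labels: np.ndarray, n: int):
    """Per-label area, centroid and second-order central moments.

    One bincount pass per raw moment; equivalent to the equivalent-ellipse
    quantities regionprops derives, but vectorized over all labels.
    """
    rr, cc = np.nonzero(labels)
    ids = labels[rr, cc]
    area = np.bincount(ids, minlength=n + 1).astype(float)
    sx = np.bincount(ids, weights=cc, minlength=n + 1)
    sy = np.bincount(ids, weights=rr, minlength=n + 1)
    sxx = np.bincount(ids, weights=cc * cc.astype(float), minlength=n + 1)
    syy = np.bincount(ids, weights=rr * rr.astype(float), minlength=n + 1)
    sxy = np.bincount(ids, weights=rr * cc.astype(float), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = sx / area
        cy = sy / area
        # central moments per unit area + 1/12 pixel-bin correction, as in
        # the normalized inertia tensor of the equivalent ellipse
        mu20 = sxx / area - cx * cx + 1.0 / 12.0
        mu02 = syy / area - cy * cy + 1.0 / 12.0
        mu11 = sxy / area - cx * cy
    return area, cx, cy, mu20, mu02, mu11


def _axis_angle_ecc(mu20, mu02, mu11):
    """Major-axis angle (deg from +x toward +y, in [0,180)) and eccentricity
    of the equivalent ellipse from second-order central moments."""
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    tr = mu20 + mu02
    d = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    l1 = (tr + d) / 2.0
    l2 = (tr - d) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ecc = np.sqrt(np.clip(1.0 - l2 / np.where(l1 > 0, l1, np.nan), 0.0, 1.0))
    return np.mod(angle, 180.0), np.nan_to_num(ecc)


def segment_nuclei(
    nuclear: np.ndarray,
    min_area_px: int = 15,
    masks: CompartmentMasks | None = None,
    min_peak_distance_px: int = 5,
) -> list[NucleusRecord]:
    """Segment nuclei from the nuclear (DAPI) channel.

    A global Otsu threshold binarizes the channel; touching blobs are split
    by a watershed on the distance transform; objects below ``min_area_px``
    are discarded.  Orientation comes from second-order central moments
    (major axis of the equivalent ellipse).  Each record is tagged with the
    compartment containing its centroid when masks are given.  An empty
    raster yields an empty list.
    """
    nuclear = np.asarray(nuclear)
    if nuclear.size == 0:
        raise ValidationError("nuclear: raster is empty")
    finite = nuclear[np.isfinite(nuclear.astype(float))]
    if finite.max() == finite.min():
        return []
    binary = nuclear > threshold_otsu(nuclear)
    if not binary.any():
        return []
    dist = ndimage.distance_transform_edt(binary)
    # smooth the distance map so the flat ridge of an elongated nucleus
    # yields one peak instead of a chain of plateau maxima
    smooth = ndimage.gaussian_filter(dist, sigma=2.0)
    peaks = peak_local_max(smooth, min_distance=min_peak_distance_px, labels=binary, exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if len(peaks) == 0:
        labels, n = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
        n = len(peaks)
    area, cx, cy, mu20, mu02, mu11 = _label_moments(labels, n)
    angle, ecc = _axis_angle_ecc(mu20, mu02, mu11)
    records: list[NucleusRecord] = []
    for lab in range(1, n + 1):
        if area[lab] < min_area_px:
            continue
        compartment = "background"
        if masks is not None:
            r = min(max(int(round(cy[lab])), 0), binary.shape[0] - 1)
            c = min(max(int(round(cx[lab])), 0), binary.shape[1] - 1)
            if masks.basal_band is not None and masks.basal_band[r, c]:
                compartment = "basal"
            elif masks.epidermis[r, c]:
                compartment = "suprabasal"
            elif masks.dermis[r, c]:
                compartment = "dermis"
        records.append(
            NucleusRecord(
                label=lab,
                centroid_x=float(cx[lab]),
                centroid_y=float(cy[lab]),
                area_px=int(area[lab]),
                major_axis_angle_deg=float(angle[lab]),
                eccentricity=float(ecc[lab]),
                compartment=compartment,
                low_confidence=float(ecc[lab]) < LOW_ECCENTRICITY,
            )
        )
    return records


def nuclei_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def area_gate(records: list[NucleusRecord], low_frac: float = 0.6, high_frac: float = 1.6) -> list[NucleusRecord]:
    """Drop segmentation artifacts by relative nucleus area.

    Objects far below the median area are watershed fragments of truncated
    nuclei; objects far above are unresolved merges of touching nuclei.
    Both carry unreliable orientations, so polarity profiling excludes them
    by default.  The gate is relative to the median area of the given
    records (typically one compartment at a time).
    """
    if not records:
        return []
    med = float(np.median([r.area_px for r in records]))
    return [r for r in records if low_frac * med <= r.area_px <= high_frac * med]


def angle_to_jde(nucleus: NucleusRecord, jde: JdePolyline) -> float:
    """Acute angle (degrees, [0, 90]) between the nucleus major axis and the
    local JDE tangent; 90 means perpendicular to the junction."""
    pts = jde.points
    d2 = (pts[:, 0] - nucleus.centroid_x) ** 2 + (pts[:, 1] - nucleus.centroid_y) ** 2
    idx = int(np.argmin(d2))
    tangent = jde.tangent_deg(idx)
    return float(acute_angle_between(nucleus.major_axis_angle_deg, tangent))


def bin_angles(angles) -> AngleHistogram:
    """Bin angles into the 18 categories [0,5), ..., [85,90]; 90 counts in
    the last bin."""
    angles = np.asarray(list(angles), dtype=float)
    if angles.size and (angles.min() < 0 or angles.max() > 90):
        raise ValidationError("angles: values must lie in [0, 90]")
    idx = np.minimum((angles // 5).astype(int), 17)
    counts = np.bincount(idx, minlength=18) if angles.size else np.zeros(18, dtype=int)
    return AngleHistogram(counts=counts, n=int(angles.size))


def classify_polarity(angle_deg: float) -> PolarityClass:
    """Map an angle to one of the three polarity classes.

    Partition: [0, 30) nearly parallel, [30, 60) oblique, [60, 90] nearly
    perpendicular (boundaries configurable via module constants).
    """
    if not 0.0 <= angle_deg <= 90.0:
        raise ValidationError("angle_deg: must be in [0, 90]")
    if angle_deg >= PERPENDICULAR_MIN:
        return PolarityClass.NEARLY_PERPENDICULAR
    if angle_deg < PARALLEL_MAX:
        return PolarityClass.NEARLY_PARALLEL
    return PolarityClass.OBLIQUE


def class_fractions(angles) -> dict[str, float]:
    angles = np.asarray(list(angles), dtype=float)
    n = angles.size
    if n == 0:
        return {c.value: float("nan") for c in PolarityClass}
    return {
        PolarityClass.NEARLY_PERPENDICULAR.value: float((angles >= PERPENDICULAR_MIN).mean()),
        PolarityClass.OBLIQUE.value: float(((angles >= PARALLEL_MAX) & (angles < PERPENDICULAR_MIN)).mean()),
        PolarityClass.NEARLY_PARALLEL.value: float((angles < PARALLEL_MAX).mean()),
    }


@dataclass
class RoiPolarity:
    """Polarity summary of one region of interest."""

    roi: tuple[float, float]  # (start_um, end_um) along the section axis
    histogram: AngleHistogram
    fractions: dict[str, float]
    angles_deg: np.ndarray
    n: int
    empty: bool


def polarity_profile(
    records: list[NucleusRecord],
    jde: JdePolyline,
    roi_intervals_um: list[tuple[float, float]],
    pixel_size_um: float,
    exclude_low_confidence: bool = False,
) -> list[RoiPolarity]:
    """Per-ROI angle histograms and class fractions for basal nuclei.

    Restricts to nuclei tagged ``basal`` whose centroid x falls inside the
    ROI interval (micrometres along the section axis).  Near-circular
    nuclei (flagged low-confidence) are included by default; set
    ``exclude_low_confidence`` to drop them.  An ROI without basal nuclei
    yields n = 0 with ``empty=True``.
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um: must be positive")
    basal = [r for r in records if r.compartment == "basal" and not (exclude_low_confidence and r.low_confidence)]
    out = []
    for start_um, end_um in roi_intervals_um:
        if start_um >= end_um:
            raise ValidationError(f"roi_intervals_um: interval ({start_um}, {end_um}) is empty")
        sel = [r for r in basal if start_um <= r.centroid_x * pixel_size_um < end_um]
        angles = np.asarray([angle_to_jde(r, jde) for r in sel], dtype=float)
        out.append(
            RoiPolarity(
                roi=(float(start_um), float(end_um)),
                histogram=bin_angles(angles),
                fractions=class_fractions(angles),
                angles_deg=angles,
                n=len(sel),
                empty=len(sel) == 0,
            )
        )
    return out
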