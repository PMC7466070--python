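"""Tissue segmentation: background threshold, compartment masks, the
dermo-epidermal junction (JDE) polyline and the basal-band mask.

All quantification stages consume the objects built here.  The section is
assumed (or brought, via :func:`orient_canonical`) into the canonical frame:
section axis horizontal, epidermis above the dermis, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptySectionError, NoJunctionError, ValidationError

#: values used in ground-truth / synthetic label maps
LABEL_BACKGROUND, LABEL_EPIDERMIS, LABEL_DERMIS = 0, 1, 2


@dataclass
class SectionImage:
    """A multi-channel section raster with physical pixel size.

    ``channels`` maps channel names (e.g. ``"dapi"``, ``"zeb1"``) to 2-D
    arrays of identical shape; ``rgb`` optionally holds an HES-like
    brightfield composite (H x W x 3, uint8).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    rgb: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if self.rgb is not None:
            shapes.add(self.rgb.shape[:2])
        if len(shapes) > 1:
            raise ValidationError("channels: all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        if self.channels:
            return next(iter(self.channels.values())).shape
        return self.rgb.shape[:2]


@dataclass
class JdePolyline:
    """Ordered pixel-coordinate trace of the dermo-epidermal junction.

    Points have strictly increasing x; ``resolution_px`` records the column
    step used when tracing.
    """

    points: np.ndarray  # (n, 2) float array of (x, y)
    resolution_px: int = 1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValidationError("points: polyline needs >= 2 (x, y) points")
        if not np.all(np.diff(self.points[:, 0]) > 0):
            raise ValidationError("points: x coordinates must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def tangent_deg(self, index: int, window: int = 6) -> float:
        """Local tangent angle (degrees from +x toward +y) by central
        difference over ``window`` neighbors each side.

        The junction trace is quantized to integer rows, so a wider window
        trades curvature fidelity for robustness to pixel jaggedness; the
        default keeps the quantization error below ~5 degrees at single-
        pixel steps while the junction curvature stays negligible on that
        scale.
        """
        i0 = max(index - window, 0)
        i1 = min(index + window, len(self.points) - 1)
        dx = self.points[i1, 0] - self.points[i0, 0]
        dy = self.points[i1, 1] - self.points[i0, 1]
        return float(np.rad2deg(np.arctan2(dy, dx))) % 180.0


@dataclass
class CompartmentMasks:
    """Pairwise-disjoint binary masks of the section compartments."""

    epidermis: np.ndarray
    dermis: np.ndarray
    background: np.ndarray
    basal_band: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.epidermis & self.dermis) or np.any(self.epidermis & self.background) or np.any(
            self.dermis & self.background
        ):
            raise ValidationError("masks: compartment masks must be pairwise disjoint")
        if self.basal_band is not None and np.any(self.basal_band & ~self.epidermis):
            raise ValidationError("basal_band: must be a subset of the epidermis mask")


def background_threshold(gray: np.ndarray, tissue_free_regions: list[tuple[int, int, int, int]], k: float = 3.0) -> float:
    """Intensity threshold separating empty space from tissue.

    The threshold is estimated from tissue-free areas of the slide as
    ``mean + k * SD`` of the pixels inside the given rectangles
    (``(row0, col0, row1, col1)``, half-open).  Pixels at or below the
    returned value are classifiable as empty space.
    """
    gray = np.asarray(gray)
    if not tissue_free_regions:
        raise ValidationError("tissue_free_regions: at least one rectangle required")
    pixels = []
    h, w = gray.shape
    for rect in tissue_free_regions:
        r0, c0, r1, c1 = (int(v) for v in rect)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValidationError(f"tissue_free_regions: rectangle {rect} empty or out of bounds for shape {gray.shape}")
        pixels.append(gray[r0:r1, c0:c1].ravel())
    sample = np.concatenate(pixels).astype(float)
    if sample.size < 100:
        raise ValidationError("tissue_free_regions: need >= 100 background pixels in total")
    return float(sample.mean() + k * sample.std())


def threshold_from_mask(gray: np.ndarray, background_mask: np.ndarray, k: float = 3.0) -> float:
    """Background threshold (mean + k*SD) over an arbitrary tissue-free mask."""
    sample = np.asarray(gray, dtype=float)[background_mask]
    if sample.size < 100:
        raise ValidationError("background_mask: need >= 100 background pixels")
    return float(sample.mean() + k * sample.std())


def segment_compartments(
    section: SectionImage,
    nuclear_channel: str = "dapi",
    threshold: float | None = None,
    label_map: np.ndarray | None = None,
    jde: "JdePolyline | None" = None,
) -> CompartmentMasks:
    """Split the section into background, epidermis and dermis.

    Tissue is everything above the background threshold on the HES
    grayscale (or the nuclear channel when no composite exists); only the
    largest connected tissue component is retained.  The epidermis/dermis
    split uses the JDE polyline when one is supplied, otherwise a labeled
    truth map (synthetic mode).
    """
    if nuclear_channel not in section.channels:
        raise ValidationError(f"nuclear_channel: channel {nuclear_channel!r} not present")
    if section.rgb is not None:
        from .cohesion import grayscale

        gray = grayscale(section.rgb).astype(float)
    else:
        gray = section.channels[nuclear_channel].astype(float)
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(gray))
    tissue = gray > threshold
    if not tissue.any():
        raise EmptySectionError("empty section: no pixel above the background threshold")
    labels, n = ndimage.label(tissue)
    if n > 1:
        sizes = ndimage.sum_labels(tissue, labels, index=np.arange(1, n + 1))
        tissue = labels == (1 + int(np.argmax(sizes)))
    # interior dark structures (intercellular spaces, dense nuclei) belong to
    # the tissue region even though they fall below the intensity threshold
    tissue = ndimage.binary_fill_holes(tissue)
    if jde is not None:
        yy = np.interp(np.arange(gray.shape[1]), jde.x, jde.y)
        below = np.arange(gray.shape[0])[:, None] > yy[None, :]
        epidermis = tissue & ~below
        dermis = tissue & below
    elif label_map is not None:
        epidermis = tissue & (label_map == LABEL_EPIDERMIS)
        dermis = tissue & (label_map == LABEL_DERMIS)
    else:
        raise ValidationError("label_map: either a JDE polyline or a labeled truth map is required to split tissue")
    background = ~(epidermis | dermis)
    return CompartmentMasks(epidermis=epidermis, dermis=dermis, background=background)


def orient_canonical(arrays: list[np.ndarray], epidermis: np.ndarray, dermis: np.ndarray):
    """Rotate a scene by a multiple of 90 degrees into the canonical frame.

    Canonical: the epidermis-to-dermis axis is vertical with the epidermis
    on top.  Returns ``(rotated_arrays, rotated_epidermis, rotated_dermis,
    k)`` where ``k`` is the number of counter-clockwise quarter turns
    applied (np.rot90 convention).  Rotations by exact quarter turns are
    lossless, so JDE-relative angles are preserved.
    """
    ec = ndimage.center_of_mass(epidermis)
    dc = ndimage.center_of_mass(dermis)
    d_row, d_col = dc[0] - ec[0], dc[1] - ec[1]
    # np.rot90 (counter-clockwise) maps a (d_row, d_col) offset to
    # (-d_col, d_row); pick k so the epidermis-to-dermis offset ends up
    # pointing down (+row)
    if abs(d_col) > abs(d_row):
        k = 3 if d_col > 0 else 1
    else:
        k = 0 if d_row > 0 else 2
    rot = lambda a: np.ascontiguousarray(np.rot90(a, k)) if k else a
    return [rot(a) for a in arrays], rot(epidermis), rot(dermis), k


def extract_jde(
    epidermis_mask: np.ndarray,
    dermis_mask: np.ndarray,
    resolution_px: int = 1,
    max_gap_columns: int = 5,
) -> JdePolyline:
    """Trace the epidermis-dermis interface as a polyline.

    For each sampled column the deepest epidermis pixel with dermis
    immediately below it defines the junction; column gaps of at most
    ``max_gap_columns`` are linearly interpolated.  A vertically stacked
    scene with the epidermis below the dermis is handled by an internal
    flip; call :func:`orient_canonical` first for 90-degree rotated scenes.
    """
    if np.any(epidermis_mask & dermis_mask):
        raise ValidationError("masks: epidermis and dermis masks overlap")
    if not epidermis_mask.any() or not dermis_mask.any():
        raise NoJunctionError("no junction: an input mask is empty")
    h, w = epidermis_mask.shape
    e_rows = ndimage.center_of_mass(epidermis_mask)[0]
    d_rows = ndimage.center_of_mass(dermis_mask)[0]
    flipped = e_rows > d_rows
    epi = epidermis_mask[::-1] if flipped else epidermis_mask
    der = dermis_mask[::-1] if flipped else dermis_mask

    # epidermis pixel with a dermis pixel directly below (within 2 rows)
    adj = epi[:-1] & (der[1:] | np.vstack([der[2:], np.zeros((1, w), bool)]))
    cols = np.arange(0, w, max(int(resolution_px), 1))
    xs, ys = [], []
    rows_idx = np.arange(h - 1)
    for c in cols:
        col_adj = adj[:, c]
        if col_adj.any():
            xs.append(float(c))
            ys.append(float(rows_idx[col_adj].max()))
    if len(xs) < 2:
        raise NoJunctionError("no junction: epidermis and dermis are nowhere adjacent")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    # interpolate across small gaps only; large gaps keep sampled points as-is
    step = max(int(resolution_px), 1)
    gaps = np.diff(xs) / step
    if np.any((gaps > 1) & (gaps <= max_gap_columns)):
        full_x = np.arange(xs[0], xs[-1] + 1, step, dtype=float)
        full_y = np.interp(full_x, xs, ys)
        keep = np.ones(len(full_x), bool)
        # drop interpolated points that fall inside gaps wider than the limit
        for i in np.nonzero(gaps > max_gap_columns)[0]:
            inside = (full_x > xs[i]) & (full_x < xs[i + 1])
            keep &= ~inside
        xs, ys = full_x[keep], full_y[keep]
    if flipped:
        ys = (h - 1) - ys
    return JdePolyline(points=np.column_stack([xs, ys]), resolution_px=step)


def basal_band(
    epidermis_mask: np.ndarray,
    jde: JdePolyline,
    band_width_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Epidermis pixels within ``band_width_um`` (Euclidean) of the JDE."""
    if band_width_um <= 0:
        raise ValidationError("band_width_um: must be positive")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um: must be positive")
    h, w = epidermis_mask.shape
    curve = np.zeros((h, w), dtype=bool)
    # rasterize the polyline densely so the distance transform sees a connected curve
    x = jde.x
    y = jde.y
    dense_x = np.arange(np.ceil(x[0]), np.floor(x[-1]) + 1)
    dense_y = np.interp(dense_x, x, y)
    cc = np.clip(dense_x.astype(int), 0, w - 1)
    rr = np.clip(np.round(dense_y).astype(int), 0, h - 1)
    curve[rr, cc] = True
    dist_px = ndimage.distance_transform_edt(~curve)
    return epidermis_mask & (dist_px * pixel_size_um <= band_width_um)
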