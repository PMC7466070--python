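"""Synthetic skin-section generator with exact ground truth.

Emulates a cross-section of regenerated human epidermis: a sinusoidal
dermo-epidermal junction (JDE), a basal layer of elongated nuclei whose
major axes point (noisily) along the local JDE normal, stratified
suprabasal layers with rounder nuclei, a sparsely nucleated dermis, dark
intercellular gaps with a controllable area fraction, fluorescence marker
channels with per-compartment intensity and positivity, and an HES-like
brightfield composite.  Inside user-declared "abnormal" intervals the
basal orientation distribution becomes uniform (loss of polarity), the gap
fraction is elevated, and marker intensity/positivity can be overridden —
the synthetic analogue of a dysplastic area.

Everything is deterministic for a fixed seed, and every structure is
recorded in a :class:`GroundTruth` so downstream measurements can be
validated pixel-for-pixel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats as sps
from scipy.optimize import brentq

from .errors import ValidationError
from .geometry import ellipse_pixels, fold_acute
from .masks import LABEL_DERMIS, LABEL_EPIDERMIS, SectionImage

COMPARTMENTS = ("basal", "suprabasal", "dermis", "gap", "background")

# HES-like composite palette (R, G, B): empty space is rendered dark so a
# tissue-free threshold separates it from tissue (see cohesion module).
_HES_COLORS = {
    "background": (12, 12, 14),
    "gap": (8, 8, 8),
    "epidermis": (228, 184, 200),
    "dermis": (214, 176, 168),
    "nucleus": (104, 78, 138),
}
_HES_NOISE_SD = 2.0


@dataclass(frozen=True)
class MarkerSpec:
    """Rendering recipe for one fluorescence marker channel.

    ``compartment_intensity`` gives the mean diffuse intensity (0-1 scale)
    per compartment.  For ``localization="nuclear"`` markers,
    ``positive_fraction`` gives the per-compartment probability that a
    nucleus is positive; positive nuclei are painted at
    ``positive_intensity``.  ``abnormal_intensity_scale`` and
    ``abnormal_positive_fraction`` override the behaviour of epidermal
    pixels/nuclei inside the section's abnormal intervals.  Membrane and
    cytoplasmic markers are rendered as diffuse compartment intensity
    (staining physics is out of scope).
    """

    name: str
    localization: str = "cytoplasmic"
    compartment_intensity: dict[str, float] = field(default_factory=dict)
    positive_fraction: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.01
    positive_intensity: float = 0.8
    abnormal_intensity_scale: float = 1.0
    abnormal_positive_fraction: dict[str, float] | None = None

    def validate(self) -> None:
        if self.localization not in ("nuclear", "membrane", "cytoplasmic"):
            raise ValidationError(f"localization: {self.localization!r} not one of nuclear/membrane/cytoplasmic")
        for key, mapping in (("compartment_intensity", self.compartment_intensity), ("positive_fraction", self.positive_fraction)):
            for comp, v in mapping.items():
                if comp not in COMPARTMENTS:
                    raise ValidationError(f"{key}: unknown compartment {comp!r}")
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{key}[{comp}]: {v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be non-negative")


@dataclass(frozen=True)
class SectionSpec:
    """Full parameterization of one synthetic section.

    Lengths are in micrometres; ``polarity_concentration`` (kappa) controls
    the angular spread of basal nuclei about the JDE normal via a wrapped
    normal with SD = 1/sqrt(kappa) radians (0 means uniform orientations).
    ``target_gap_fraction`` is the intercellular-space area fraction inside
    the epidermis: applied to the whole epidermis when there are no
    abnormal intervals, and inside abnormal intervals otherwise (with
    ``normal_gap_fraction`` outside them).
    """

    width_px: int = 1600
    height_px: int = 400
    pixel_size_um: float = 0.5
    jde_amplitude_um: float = 20.0
    jde_wavelength_um: float = 300.0
    epidermis_thickness_um: float = 90.0
    basal_nucleus_axis_ratio: float = 2.5
    polarity_concentration: float = 8.0
    target_gap_fraction: float = 0.02
    normal_gap_fraction: float = 0.02
    marker_specs: tuple[MarkerSpec, ...] = ()
    abnormal_intervals_um: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    # fixture-scale choices (not study facts): ~150 basal nuclei per 800 um
    basal_nucleus_spacing_um: float = 5.33
    basal_nucleus_major_um: float = 9.0
    basal_band_um: float = 15.0
    suprabasal_density_per_um2: float = 1.0 / 250.0
    dermal_density_per_um2: float = 1.0 / 600.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")
        for name in (
            "pixel_size_um",
            "jde_wavelength_um",
            "epidermis_thickness_um",
            "basal_nucleus_spacing_um",
            "basal_nucleus_major_um",
            "basal_band_um",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")
        if self.jde_amplitude_um < 0:
            raise ValidationError("jde_amplitude_um: must be non-negative")
        if self.basal_nucleus_axis_ratio < 1:
            raise ValidationError("basal_nucleus_axis_ratio: must be >= 1")
        if self.polarity_concentration < 0:
            raise ValidationError("polarity_concentration: must be non-negative")
        for name in ("target_gap_fraction", "normal_gap_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name}: must be in [0, 1]")
        length = self.width_px * self.pixel_size_um
        for iv in self.abnormal_intervals_um:
            a, b = iv
            if not (0 <= a < b <= length):
                raise ValidationError(f"abnormal_intervals_um: interval {iv} outside [0, {length}]")
        needed = (self.epidermis_thickness_um + 2 * self.jde_amplitude_um) / self.pixel_size_um + 20
        if self.height_px < needed:
            raise ValidationError(f"height_px: {self.height_px} too small for the requested geometry (needs >= {int(np.ceil(needed))})")
        for ms in self.marker_specs:
            ms.validate()

    @property
    def section_length_um(self) -> float:
        return self.width_px * self.pixel_size_um

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_specs"] = [dataclasses.asdict(ms) for ms in self.marker_specs]
        d["abnormal_intervals_um"] = [list(iv) for iv in self.abnormal_intervals_um]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SectionSpec":
        d = dict(d)
        d["marker_specs"] = tuple(MarkerSpec(**ms) if not isinstance(ms, MarkerSpec) else ms for ms in d.get("marker_specs", ()))
        d["abnormal_intervals_um"] = tuple(tuple(iv) for iv in d.get("abnormal_intervals_um", ()))
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact truth for a generated section."""

    spec: SectionSpec
    jde_xy: np.ndarray  # (w, 2) float: (x, y) per column
    label_map: np.ndarray  # uint8: 0 background, 1 epidermis, 2 dermis
    basal_band_mask: np.ndarray
    gap_mask: np.ndarray
    nucleus_labels: np.ndarray  # int32 label image of rendered nuclei
    realized_gap_fraction: float
    region_gap_fractions: list[dict]
    nuclei: pd.DataFrame  # label, x, y, compartment, angle_jde_deg, axis_angle_deg, area_px, positive_<marker>...
    marker_means: dict[str, dict[str, float]]
    abnormal_intervals_um: tuple[tuple[float, float], ...]

    @property
    def epidermis_mask(self) -> np.ndarray:
        return self.label_map == LABEL_EPIDERMIS

    @property
    def dermis_mask(self) -> np.ndarray:
        return self.label_map == LABEL_DERMIS


# ---------------------------------------------------------------------------
# analytic orientation distribution (closed-form oracle for the generator)

def _sigma_deg(concentration: float) -> float:
    return float(np.rad2deg(1.0 / np.sqrt(concentration)))


def angle_cdf(t_deg: float, concentration: float) -> float:
    """P(angle-to-JDE <= t) for basal nuclei at the given concentration.

    The nucleus axis deviates from the JDE normal by a wrapped normal with
    SD = 1/sqrt(concentration) radians; the angle to the junction tangent is
    the acute fold of (90 + deviation).  Concentration 0 means uniform on
    [0, 90].
    """
    t = float(t_deg)
    if not 0.0 <= t <= 90.0:
        raise ValidationError("t_deg: must be in [0, 90]")
    if concentration == 0:
        return t / 90.0
    s = _sigma_deg(concentration)
    kmax = int(np.ceil((8 * s + 90) / 180.0)) + 1
    total = 0.0
    for k in range(-kmax, kmax + 1):
        base = 180.0 * k
        total += sps.norm.cdf((base + t - 90.0) / s) - sps.norm.cdf((base - 90.0) / s)
        total += sps.norm.cdf((base + 90.0) / s) - sps.norm.cdf((base + 90.0 - t) / s)
    return float(min(max(total, 0.0), 1.0))


def analytic_angle_mass(concentration: float, lo_deg: float, hi_deg: float) -> float:
    """Probability mass of the angle-to-JDE distribution on [lo, hi]."""
    if lo_deg > hi_deg:
        raise ValidationError("lo_deg: must not exceed hi_deg")
    return angle_cdf(hi_deg, concentration) - angle_cdf(lo_deg, concentration)


def analytic_angle_median(concentration: float) -> float:
    """Median of the angle-to-JDE distribution in degrees."""
    if concentration == 0:
        return 45.0
    return float(brentq(lambda t: angle_cdf(t, concentration) - 0.5, 0.0, 90.0))


# ---------------------------------------------------------------------------

def _abnormal_column_mask(spec: SectionSpec) -> np.ndarray:
    cols = (np.arange(spec.width_px) + 0.5) * spec.pixel_size_um
    mask = np.zeros(spec.width_px, dtype=bool)
    for a, b in spec.abnormal_intervals_um:
        mask |= (cols >= a) & (cols < b)
    return mask


def _place_sparse_nuclei(rng, eligible_rc, count, existing_xy, min_dist_px):
    """Uniformly sample nucleus centers from eligible pixels, rejecting
    candidates closer than min_dist_px to any accepted/existing center."""
    centers = []
    if len(eligible_rc[0]) == 0 or count <= 0:
        return centers
    taken = list(existing_xy)
    order = rng.permutation(len(eligible_rc[0]))
    for idx in order:
        if len(centers) >= count:
            break
        y = float(eligible_rc[0][idx])
        x = float(eligible_rc[1][idx])
        if taken:
            arr = np.asarray(taken)
            if np.min((arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2) < min_dist_px**2:
                continue
        centers.append((x, y))
        taken.append((x, y))
    return centers


def generate_section(spec: SectionSpec) -> tuple[SectionImage, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Deterministic for a fixed ``spec.seed``: independent RNG sub-streams
    per structural element keep nucleus placement stable when marker specs
    change.
    """
    px = spec.pixel_size_um
    w, h = spec.width_px, spec.height_px
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(6 + len(spec.marker_specs))
    rng_phase, rng_basal, rng_supra, rng_dermal, rng_gap, rng_noise = (np.random.default_rng(c) for c in children[:6])
    marker_rngs = [np.random.default_rng(c) for c in children[6:]]

    amp = spec.jde_amplitude_um / px
    wavelength = spec.jde_wavelength_um / px
    thickness = spec.epidermis_thickness_um / px
    margin_top = 8.0
    jde_base = margin_top + thickness + amp
    phase = rng_phase.uniform(0.0, 2.0 * np.pi)

    def jde_row_at(x):
        return jde_base + amp * np.sin(2.0 * np.pi * np.asarray(x, dtype=float) / wavelength + phase)

    def tangent_deg_at(x):
        slope = amp * (2.0 * np.pi / wavelength) * np.cos(2.0 * np.pi * np.asarray(x, dtype=float) / wavelength + phase)
        return np.rad2deg(np.arctan2(slope, 1.0)) % 180.0

    xs_cols = np.arange(w, dtype=float)
    jde_rows = jde_row_at(xs_cols)
    surface_rows = jde_rows - thickness
    rows = np.arange(h, dtype=float)[:, None]
    label_map = np.zeros((h, w), dtype=np.uint8)
    label_map[(rows > surface_rows[None, :]) & (rows <= jde_rows[None, :])] = LABEL_EPIDERMIS
    label_map[rows > jde_rows[None, :]] = LABEL_DERMIS
    epidermis = label_map == LABEL_EPIDERMIS
    dermis = label_map == LABEL_DERMIS

    # truth basal band: epidermis within basal_band_um vertically above the JDE
    depth = jde_rows[None, :] - rows  # px above the junction
    basal_band_mask = epidermis & (depth * px <= spec.basal_band_um) & (depth >= 0)

    abnormal_cols = _abnormal_column_mask(spec)

    # ---- basal nuclei along the junction -------------------------------
    sigma_deg = None if spec.polarity_concentration == 0 else _sigma_deg(spec.polarity_concentration)
    spacing = spec.basal_nucleus_spacing_um / px
    a_basal = (spec.basal_nucleus_major_um / 2.0) / px
    nuclei: list[dict] = []
    x_pos = spacing / 2.0
    while x_pos < w - 1:
        x = x_pos + rng_basal.uniform(-0.15, 0.15) * spacing
        x_pos += spacing
        x = float(np.clip(x, 1.0, w - 2.0))
        tangent = float(tangent_deg_at(x))
        a = a_basal * rng_basal.uniform(0.9, 1.1)
        b = a / spec.basal_nucleus_axis_ratio
        y = float(jde_row_at(x)) - rng_basal.uniform(1.0, 1.35) * a
        in_abn = abnormal_cols[int(x)]
        if in_abn or sigma_deg is None:
            angle_jde = float(rng_basal.uniform(0.0, 90.0))
            sign = 1.0 if rng_basal.random() < 0.5 else -1.0
            axis = (tangent + sign * angle_jde) % 180.0
        else:
            dev = float(rng_basal.normal(0.0, sigma_deg))
            axis = (tangent + 90.0 + dev) % 180.0
            angle_jde = float(fold_acute(90.0 + dev))
        nuclei.append(
            dict(x=x, y=y, a=a, b=b, axis=axis, angle_jde=angle_jde, compartment="basal", abnormal=bool(in_abn))
        )

    # ---- suprabasal and dermal nuclei ----------------------------------
    upper_epi = epidermis & ~basal_band_mask & (depth * px <= spec.epidermis_thickness_um - 4.0)
    n_supra = int(upper_epi.sum() * px * px * spec.suprabasal_density_per_um2)
    existing = [(n["x"], n["y"]) for n in nuclei]
    min_dist = 0.9 * spec.basal_nucleus_major_um / px
    for x, y in _place_sparse_nuclei(rng_supra, np.nonzero(upper_epi), n_supra, existing, min_dist):
        a = (3.0 / px) * rng_supra.uniform(0.85, 1.15)
        b = a / 1.4
        axis = float(rng_supra.uniform(0.0, 180.0))
        tangent = float(tangent_deg_at(x))
        nuclei.append(
            dict(x=x, y=y, a=a, b=b, axis=axis, angle_jde=float(fold_acute(axis - tangent)), compartment="suprabasal", abnormal=bool(abnormal_cols[int(x)]))
        )
        existing.append((x, y))
    dermal_region = dermis & (rows > (jde_rows[None, :] + 3.0 / px)) & (rows < h - 3)
    n_dermal = int(dermis.sum() * px * px * spec.dermal_density_per_um2)
    for x, y in _place_sparse_nuclei(rng_dermal, np.nonzero(dermal_region), n_dermal, existing, min_dist):
        a = (3.2 / px) * rng_dermal.uniform(0.85, 1.15)
        b = a / 1.6
        axis = float(rng_dermal.uniform(0.0, 180.0))
        tangent = float(tangent_deg_at(x))
        nuclei.append(
            dict(x=x, y=y, a=a, b=b, axis=axis, angle_jde=float(fold_acute(axis - tangent)), compartment="dermis", abnormal=bool(abnormal_cols[int(x)]))
        )
        existing.append((x, y))

    # ---- paint nuclei ---------------------------------------------------
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    for i, nuc in enumerate(nuclei, start=1):
        rr, cc = ellipse_pixels(nuc["y"], nuc["x"], nuc["a"], nuc["b"], nuc["axis"], (h, w))
        free = nucleus_labels[rr, cc] == 0
        nucleus_labels[rr[free], cc[free]] = i
        nuc["label"] = i
        nuc["area_px"] = int(free.sum())
    nucleus_mask = nucleus_labels > 0

    # ---- intercellular gaps (rejection-placed dark ellipses) ------------
    gap_mask = np.zeros((h, w), dtype=bool)
    region_gap_fractions: list[dict] = []
    if spec.abnormal_intervals_um:
        regions = [(abnormal_cols, spec.target_gap_fraction, "abnormal"), (~abnormal_cols, spec.normal_gap_fraction, "normal")]
    else:
        regions = [(np.ones(w, dtype=bool), spec.target_gap_fraction, "whole")]
    for colmask, target, name in regions:
        region_epi = epidermis & colmask[None, :]
        n_epi = int(region_epi.sum())
        if n_epi == 0:
            continue
        eligible = np.nonzero(region_epi & ~nucleus_mask)
        n_gap = int((gap_mask & region_epi).sum())
        attempts = 0
        while n_gap < target * n_epi and attempts < 100_000 and len(eligible[0]):
            attempts += 1
            j = rng_gap.integers(len(eligible[0]))
            cy, cx = float(eligible[0][j]), float(eligible[1][j])
            ga = rng_gap.uniform(1.5, 4.0) / px
            gb = ga * rng_gap.uniform(0.45, 1.0)
            gangle = rng_gap.uniform(0.0, 180.0)
            rr, cc = ellipse_pixels(cy, cx, ga, gb, gangle, (h, w))
            if len(rr) == 0:
                continue
            keep = region_epi[rr, cc]
            rr, cc = rr[keep], cc[keep]
            if len(rr) == 0 or nucleus_mask[rr, cc].any():
                continue
            new = ~gap_mask[rr, cc]
            gap_mask[rr[new], cc[new]] = True
            n_gap += int(new.sum())
        region_gap_fractions.append(dict(region=name, target=float(target), realized=n_gap / n_epi, epidermis_px=n_epi))
    epi_total = int(epidermis.sum())
    realized_gap_fraction = float(gap_mask.sum() / epi_total) if epi_total else 0.0

    # ---- channels --------------------------------------------------------
    channels: dict[str, np.ndarray] = {}
    dapi = np.full((h, w), 0.02, dtype=np.float64)
    lab_rr, lab_cc = np.nonzero(nucleus_labels)
    lab_vals = nucleus_labels[lab_rr, lab_cc]
    intensities = np.clip(rng_noise.normal(0.75, 0.04, size=len(nuclei) + 1), 0.5, 0.95)
    dapi[lab_rr, lab_cc] = intensities[lab_vals]
    dapi += rng_noise.normal(0.0, 0.01, size=(h, w))
    channels["dapi"] = (np.clip(dapi, 0.0, 1.0) * 65535.0).round().astype(np.uint16)

    comp_masks = {
        "basal": basal_band_mask & ~gap_mask,
        "suprabasal": epidermis & ~basal_band_mask & ~gap_mask,
        "dermis": dermis,
        "gap": gap_mask,
        "background": label_map == 0,
    }
    marker_means: dict[str, dict[str, float]] = {}
    positivity: dict[str, np.ndarray] = {}
    for ms, mrng in zip(spec.marker_specs, marker_rngs):
        img = np.zeros((h, w), dtype=np.float64)
        for comp, m in comp_masks.items():
            img[m] = ms.compartment_intensity.get(comp, 0.0)
        if spec.abnormal_intervals_um and ms.abnormal_intensity_scale != 1.0:
            scale_region = (epidermis & ~gap_mask) & abnormal_cols[None, :]
            img[scale_region] *= ms.abnormal_intensity_scale
        pos = np.zeros(len(nuclei), dtype=bool)
        if ms.localization == "nuclear":
            for i, nuc in enumerate(nuclei):
                frac_map = ms.positive_fraction
                if nuc["abnormal"] and ms.abnormal_positive_fraction is not None:
                    frac_map = ms.abnormal_positive_fraction
                frac = frac_map.get(nuc["compartment"], 0.0)
                if frac > 0 and mrng.random() < frac:
                    pos[i] = True
            if pos.any():
                pos_labels = np.zeros(len(nuclei) + 1, dtype=bool)
                pos_labels[1:] = pos
                sel = pos_labels[lab_vals]
                img[lab_rr[sel], lab_cc[sel]] = ms.positive_intensity
        positivity[ms.name] = pos
        if ms.noise_sd > 0:
            img += mrng.normal(0.0, ms.noise_sd, size=(h, w))
        arr = (np.clip(img, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
        channels[ms.name] = arr
        marker_means[ms.name] = {comp: float(arr[m].mean() / 65535.0) if m.any() else 0.0 for comp, m in comp_masks.items()}

    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = _HES_COLORS["background"]
    rgb[epidermis] = _HES_COLORS["epidermis"]
    rgb[dermis] = _HES_COLORS["dermis"]
    rgb[gap_mask] = _HES_COLORS["gap"]
    rgb[nucleus_mask] = _HES_COLORS["nucleus"]
    rgb += rng_noise.normal(0.0, _HES_NOISE_SD, size=(h, w, 3))
    rgb_u8 = np.clip(rgb, 0, 255).round().astype(np.uint8)

    records = []
    for i, nuc in enumerate(nuclei):
        rec = dict(
            label=nuc["label"],
            x=nuc["x"],
            y=nuc["y"],
            compartment=nuc["compartment"],
            angle_jde_deg=nuc["angle_jde"],
            axis_angle_deg=nuc["axis"],
            area_px=nuc["area_px"],
            abnormal=nuc["abnormal"],
        )
        for name, pos in positivity.items():
            rec[f"positive_{name}"] = bool(pos[i])
        records.append(rec)
    nuclei_df = pd.DataFrame.from_records(records)

    section = SectionImage(channels=channels, pixel_size_um=px, rgb=rgb_u8, meta={"seed": spec.seed})
    truth = GroundTruth(
        spec=spec,
        jde_xy=np.column_stack([xs_cols, jde_rows]),
        label_map=label_map,
        basal_band_mask=basal_band_mask,
        gap_mask=gap_mask,
        nucleus_labels=nucleus_labels,
        realized_gap_fraction=realized_gap_fraction,
        region_gap_fractions=region_gap_fractions,
        nuclei=nuclei_df,
        marker_means=marker_means,
        abnormal_intervals_um=spec.abnormal_intervals_um,
    )
    return section, truth


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(section: SectionImage, truth: GroundTruth, directory: str | Path) -> dict:
    """Write a section and its truth to ``directory`` (TIFF + JSON + CSV).

    Returns the manifest (also stored as ``manifest.json``) listing every
    file and the generating spec, from which :func:`generate_section`
    reproduces the fixture bit-for-bit.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"directory: {directory} does not exist or is not a directory")
    files: dict[str, str] = {}
    for name, arr in section.channels.items():
        fname = f"channel_{name}.tif"
        tifffile.imwrite(directory / fname, arr)
        files[f"channel:{name}"] = fname
    if section.rgb is not None:
        tifffile.imwrite(directory / "hes_rgb.tif", section.rgb)
        files["rgb"] = "hes_rgb.tif"
    for name, arr in (
        ("label_map", truth.label_map.astype(np.uint8)),
        ("gap_mask", (truth.gap_mask * 255).astype(np.uint8)),
        ("basal_band", (truth.basal_band_mask * 255).astype(np.uint8)),
        ("nucleus_labels", truth.nucleus_labels.astype(np.int32)),
    ):
        tifffile.imwrite(directory / f"{name}.tif", arr)
        files[name] = f"{name}.tif"
    truth.nuclei.to_csv(directory / "nuclei.csv", index=False)
    files["nuclei"] = "nuclei.csv"
    truth_json = dict(
        jde_xy=truth.jde_xy.tolist(),
        realized_gap_fraction=truth.realized_gap_fraction,
        region_gap_fractions=truth.region_gap_fractions,
        marker_means=truth.marker_means,
        abnormal_intervals_um=[list(iv) for iv in truth.abnormal_intervals_um],
    )
    (directory / "truth.json").write_text(json.dumps(truth_json))
    files["truth"] = "truth.json"
    manifest = dict(files=files, spec=truth.spec.to_dict(), pixel_size_um=section.pixel_size_um)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixture(directory: str | Path) -> tuple[SectionImage, GroundTruth]:
    """Load a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = SectionSpec.from_dict(manifest["spec"])
    channels = {}
    rgb = None
    for key, fname in manifest["files"].items():
        if key.startswith("channel:"):
            channels[key.split(":", 1)[1]] = tifffile.imread(directory / fname)
        elif key == "rgb":
            rgb = tifffile.imread(directory / fname)
    label_map = tifffile.imread(directory / manifest["files"]["label_map"])
    gap_mask = tifffile.imread(directory / manifest["files"]["gap_mask"]) > 0
    basal = tifffile.imread(directory / manifest["files"]["basal_band"]) > 0
    nucleus_labels = tifffile.imread(directory / manifest["files"]["nucleus_labels"]).astype(np.int32)
    nuclei = pd.read_csv(directory / manifest["files"]["nuclei"])
    tj = json.loads((directory / manifest["files"]["truth"]).read_text())
    section = SectionImage(channels=channels, pixel_size_um=manifest["pixel_size_um"], rgb=rgb)
    truth = GroundTruth(
        spec=spec,
        jde_xy=np.asarray(tj["jde_xy"], dtype=float),
        label_map=label_map,
        basal_band_mask=basal,
        gap_mask=gap_mask,
        nucleus_labels=nucleus_labels,
        realized_gap_fraction=tj["realized_gap_fraction"],
        region_gap_fractions=tj["region_gap_fractions"],
        nuclei=nuclei,
        marker_means=tj["marker_means"],
        abnormal_intervals_um=tuple(tuple(iv) for iv in tj["abnormal_intervals_um"]),
    )
    return section, truth
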