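"""End-to-end per-section analysis and synthetic cohort experiments.

`analyze_section` chains the full measurement path — background threshold,
compartment masks, JDE extraction, basal band, nucleus segmentation,
polarity, cohesion and (optionally) marker quantification — and returns
one object holding every intermediate plus a flat metric dict.

`control_spec` / `dysplastic_spec` define the two study-like synthetic
conditions (normal polarity and low gap fraction vs. uniform orientations
and elevated gaps inside abnormal intervals) used for cohort-level
simulation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohesion as coh
from . import markers as mk
from . import polarity as pol
from .masks import (
    CompartmentMasks,
    JdePolyline,
    SectionImage,
    basal_band,
    extract_jde,
    orient_canonical,
    segment_compartments,
    threshold_from_mask,
)
from .synthetic import SectionSpec, generate_section


@dataclass
class SectionAnalysis:
    section: SectionImage
    masks: CompartmentMasks
    jde: JdePolyline
    nuclei: list[pol.NucleusRecord]
    nucleus_labels: np.ndarray | None
    roi_polarity: list[pol.RoiPolarity]
    cohesion: coh.CohesionResult | None
    marker_levels: dict[str, mk.MarkerLevel] = field(default_factory=dict)
    positive_cells: dict[str, mk.PositiveCellResult] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)


def analyze_section(
    section: SectionImage,
    label_map: np.ndarray | None = None,
    roi_intervals_um: list[tuple[float, float]] | None = None,
    band_width_um: float = 15.0,
    min_nucleus_area_px: int = 15,
    min_gap_object_px: int = 8,
    threshold_k: float = 3.0,
    compute_cohesion: bool = True,
    canonicalize: bool = True,
) -> SectionAnalysis:
    """Run the full quantification pipeline on one section.

    ``label_map`` (synthetic/annotated mode) supplies the epidermis/dermis
    split; the scene is first rotated into the canonical frame (epidermis
    above dermis, section axis horizontal), which leaves JDE-relative
    angles unchanged.
    """
    channels = dict(section.channels)
    rgb = section.rgb
    comp = segment_compartments(section, label_map=label_map, threshold=None)
    if canonicalize:
        names = list(channels)
        arrays = [channels[n] for n in names]
        if rgb is not None:
            arrays.append(rgb)
        if label_map is not None:
            arrays.append(label_map)
        arrays, epi, der, _k = orient_canonical(arrays, comp.epidermis, comp.dermis)
        if label_map is not None:
            label_map = arrays.pop()
        if rgb is not None:
            rgb = arrays.pop()
        channels = dict(zip(names, arrays))
        bg = ~(epi | der)
        comp = CompartmentMasks(epidermis=epi, dermis=der, background=bg)
        section = SectionImage(channels=channels, pixel_size_um=section.pixel_size_um, rgb=rgb, meta=section.meta)

    px = section.pixel_size_um
    jde = extract_jde(comp.epidermis, comp.dermis)
    band = basal_band(comp.epidermis, jde, band_width_um, px)
    comp = CompartmentMasks(epidermis=comp.epidermis, dermis=comp.dermis, background=comp.background, basal_band=band)

    dapi = channels["dapi"]
    nuclei = pol.segment_nuclei(dapi, min_area_px=min_nucleus_area_px, masks=comp)
    width_um = section.shape[1] * px
    rois = roi_intervals_um if roi_intervals_um is not None else [(0.0, width_um)]
    # gate basal nuclei by relative area: fragments and merges carry
    # unreliable orientations
    basal = pol.area_gate([r for r in nuclei if r.compartment == "basal"])
    gated = basal + [r for r in nuclei if r.compartment != "basal"]
    roi_res = pol.polarity_profile(gated, jde, rois, px)

    metrics: dict[str, float] = {}
    all_angles = np.concatenate([r.angles_deg for r in roi_res]) if roi_res else np.empty(0)
    if all_angles.size:
        fr = pol.class_fractions(all_angles)
        metrics["n_basal"] = float(all_angles.size)
        metrics["median_angle_deg"] = float(np.median(all_angles))
        metrics["perpendicular_fraction"] = fr[pol.PolarityClass.NEARLY_PERPENDICULAR.value]
        metrics["oblique_fraction"] = fr[pol.PolarityClass.OBLIQUE.value]
        metrics["parallel_fraction"] = fr[pol.PolarityClass.NEARLY_PARALLEL.value]

    cohesion_result = None
    if compute_cohesion and rgb is not None:
        gray = coh.grayscale(rgb)
        thr = threshold_from_mask(gray, comp.background, k=threshold_k)
        cohesion_result = coh.space_mask(gray, comp.epidermis, thr, min_object_px=min_gap_object_px)
        metrics["cohesion_score_au"] = cohesion_result.score_au

    return SectionAnalysis(
        section=section,
        masks=comp,
        jde=jde,
        nuclei=nuclei,
        nucleus_labels=None,
        roi_polarity=roi_res,
        cohesion=cohesion_result,
        metrics=metrics,
    )


# ---------------------------------------------------------------------------
# synthetic study conditions

def control_spec(seed: int, **overrides) -> SectionSpec:
    """A normal regenerated-epidermis section: concentrated perpendicular
    basal polarity and a low intercellular-gap fraction."""
    params = dict(
        width_px=700,
        height_px=170,
        pixel_size_um=1.0,
        jde_amplitude_um=12.0,
        jde_wavelength_um=250.0,
        epidermis_thickness_um=80.0,
        polarity_concentration=8.0,
        target_gap_fraction=0.02,
        basal_nucleus_spacing_um=7.0,
        basal_nucleus_major_um=8.0,
        seed=seed,
    )
    params.update(overrides)
    return SectionSpec(**params)


def dysplastic_spec(seed: int, **overrides) -> SectionSpec:
    """A section carrying a dysplastic-like abnormal interval: uniform
    basal orientations and an elevated gap fraction inside it."""
    params = dict(
        width_px=700,
        height_px=170,
        pixel_size_um=1.0,
        jde_amplitude_um=12.0,
        jde_wavelength_um=250.0,
        epidermis_thickness_um=80.0,
        polarity_concentration=8.0,
        target_gap_fraction=0.12,
        normal_gap_fraction=0.02,
        abnormal_intervals_um=((150.0, 550.0),),
        basal_nucleus_spacing_um=7.0,
        basal_nucleus_major_um=8.0,
        seed=seed,
    )
    params.update(overrides)
    return SectionSpec(**params)


def section_metrics(spec: SectionSpec, **analyze_kwargs) -> dict[str, float]:
    """Generate one section from ``spec`` and return its metric dict."""
    section, truth = generate_section(spec)
    res = analyze_section(section, label_map=truth.label_map, **analyze_kwargs)
    return res.metrics


def simulate_cohorts(
    n_sections: int,
    seed: int,
    spec_a=control_spec,
    spec_b=dysplastic_spec,
    **analyze_kwargs,
) -> pd.DataFrame:
    """Measure two synthetic cohorts section by section.

    Returns a tidy table (cohort, section, metric, value) ready for
    :func:`dermaquant.stats.cohort_compare`-style pooling.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, spec_fn in (("a", spec_a), ("b", spec_b)):
        for i in range(n_sections):
            m = section_metrics(spec_fn(int(rng.integers(2**31 - 1))), **analyze_kwargs)
            for name, value in m.items():
                rows.append(dict(cohort=cohort, section=i, metric=name, value=value))
    return pd.DataFrame(rows)
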