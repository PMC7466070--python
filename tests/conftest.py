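import numpy as np
import pytest

from dermaquant.pipeline import analyze_section
from dermaquant.synthetic import MarkerSpec, SectionSpec, generate_section

VANGL2 = MarkerSpec(
    name="vangl2",
    localization="membrane",
    compartment_intensity={"basal": 0.6, "suprabasal": 0.15, "dermis": 0.05, "gap": 0.0, "background": 0.01},
    abnormal_intensity_scale=0.5,
)

ZEB1 = MarkerSpec(
    name="zeb1",
    localization="nuclear",
    compartment_intensity={"basal": 0.03, "suprabasal": 0.03, "dermis": 0.03, "gap": 0.0, "background": 0.01},
    positive_fraction={"dermis": 0.9},
    abnormal_positive_fraction={"dermis": 0.9, "basal": 0.18, "suprabasal": 0.18},
)


@pytest.fixture(scope="session")
def normal_fixture():
    """A default-scale normal section with both marker channels."""
    spec = SectionSpec(seed=41, marker_specs=(VANGL2, ZEB1))
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def normal_analysis(normal_fixture):
    _, section, truth = normal_fixture
    return analyze_section(section, label_map=truth.label_map)


@pytest.fixture(scope="session")
def dysplastic_fixture():
    """A section with an abnormal interval: uniform polarity, elevated gaps,
    halved basal VANGL2 and ZEB1-positive keratinocytes inside it."""
    spec = SectionSpec(
        seed=42,
        marker_specs=(VANGL2, ZEB1),
        abnormal_intervals_um=((200.0, 600.0),),
        target_gap_fraction=0.15,
        normal_gap_fraction=0.02,
    )
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def dysplastic_analysis(dysplastic_fixture):
    _, section, truth = dysplastic_fixture
    return analyze_section(section, label_map=truth.label_map)


def match_nuclei(truth_df, records, radius_px=5.0):
    """Greedy nearest matching of truth nuclei to measured records."""
    from scipy.spatial import cKDTree

    if not records:
        return np.array([], dtype=int), np.full(len(truth_df), -1)
    tree = cKDTree(np.c_[[r.centroid_x for r in records], [r.centroid_y for r in records]])
    d, idx = tree.query(np.c_[truth_df.x, truth_df.y], distance_upper_bound=radius_px)
    matched = np.isfinite(d)
    return np.nonzero(matched)[0], np.where(matched, idx, -1)
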