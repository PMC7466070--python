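# Methods

## Scope and model

The package quantifies four readouts of dysplastic change in stratified
epidermis from 2-D section images: basal-nucleus orientation relative to the
dermo-epidermal junction (JDE), the area fraction of expanded intercellular
("non-cohesive") spaces, semi-quantitative immunofluorescence levels and
positive-cell fractions, and interval-based morphometry of abnormal section
length, compared across cohorts with the Mann–Whitney U test. No mechanistic
model is fitted; every quantity is a deterministic measurement of the input
raster plus a nonparametric two-sample test.

Coordinate convention throughout: 0-based pixel indices, origin top-left,
x = column, y = row increasing downward; undirected line angles in degrees
from the +x axis toward +y, in [0, 180); JDE-relative angles folded to
[0, 90], where 90° means perpendicular to the junction.

## Pipeline

1. **Background threshold.** t = mean + k·SD of pixels in tissue-free slide
   rectangles (default k = 3, exposed). The synthetic composite renders
   empty space dark, so pixels ≤ t are space; a CLI `--invert` flag covers
   bright-space imagery.
2. **Compartments.** Tissue = largest connected component above t, with
   interior holes re-filled (intercellular spaces and dense nuclei belong to
   the tissue region). The epidermis/dermis split comes from a JDE polyline
   when available, otherwise a labeled map (synthetic/annotated mode).
   Scenes are first rotated by a multiple of 90° into a canonical frame
   (section axis horizontal, epidermis above dermis) — quarter-turn
   rotations are lossless, so JDE-relative angles are unchanged.
3. **JDE polyline.** Per column, the deepest epidermis pixel with dermis
   immediately below; gaps ≤ 5 columns are interpolated, larger gaps split
   the trace. The local tangent is a central difference over ±6 columns:
   the trace is quantized to integer rows, so a 2-px baseline would carry
   ~26° quantization noise while ±6 keeps it below ~5° at negligible
   curvature error (junction wavelengths are hundreds of pixels).
4. **Basal band.** Epidermis pixels within 15 µm (Euclidean, default,
   exposed) of the polyline. The band width is a configuration choice, not
   a biological constant.
5. **Nuclei.** Otsu threshold on the DAPI channel, watershed on the
   (σ = 2 px smoothed) distance transform to split touching nuclei, objects
   < 15 px discarded. Orientation and eccentricity come from second-order
   central moments of each label (equivalent ellipse; the 1/12 pixel-bin
   correction is included). Nuclei with eccentricity < 0.05 are kept but
   flagged low-confidence. For polarity profiling, basal records are
   area-gated to [0.6, 1.6] × median area: objects below the gate are
   watershed fragments of truncated nuclei and objects above are unresolved
   merges of touching neighbours, both with unreliable orientations.
6. **Polarity.** Angle to the tangent at the nearest polyline vertex,
   folded to [0, 90]; 18 bins of 5° with the last bin closed so 90° is
   countable; classes partitioned at 30° and 60° (boundaries exposed; 30°
   belongs to oblique, 60° to nearly perpendicular by the half-open
   convention).
7. **Cohesion.** Space mask computed once over the whole epidermis
   (components < 20 px dropped as noise by default; 8 px in the bundled
   pipeline profile, both exposed), then counted per region so that a
   partition's pixel counts sum exactly to the whole-section counts. Score
   is normalized per epidermis area (×100) to make sections of different
   lengths comparable.
8. **Markers.** Levels are background-subtracted intensity sums over a
   mask; the background estimate is the median outside tissue. DAPI
   normalization is Σmarker/ΣDAPI over the same mask — exact for a
   pixelwise-proportional channel and invariant to a common gain.
   Positivity: per-nucleus *mean* intensity (less sensitive to single
   bright pixels than max) against mean + 3·SD of a known-negative nucleus
   population, mirroring a no-primary-antibody control; the rule and k are
   exposed. Epidermis-wide levels are not DAPI-normalized by default
   (switchable).
9. **Morphometry & statistics.** Abnormal intervals are merged before
   summing, so the percent of section length is invariant to reordering
   and splitting. A xenograft is classified from the mean of its sections'
   percentages against a 12% threshold, boundary inclusive ("at least
   12%"); max/median summaries are available since the aggregation rule is
   a convention. Mann–Whitney U: exact enumeration when n₁, n₂ ≤ 8 and the
   pooled sample is tie-free, otherwise the normal approximation with
   midranks, tie correction and continuity correction (matching common
   Prism behaviour); constant identical samples return p = 1 with a
   degeneracy flag. Cohort comparisons pool per-section/region values into
   dot-plot-style samples by default; a per-xenograft-aggregated variant
   avoids pseudo-replication but is opt-in, to stay comparable with the
   pooled convention.

## Synthetic sections

The generator emulates a cross-section of regenerated skin: a sinusoidal
JDE (default amplitude 20 µm, wavelength 300 µm), an epidermis of constant
thickness above it, dermis below, and background elsewhere. Basal nuclei
(major axis 9 µm, axis ratio 2.5, ~150 per 800 µm by default — a fixture
choice, not a biological claim) sit just above the junction with their
major axes deviating from the local JDE normal by a wrapped normal of
SD = 1/√κ radians; κ = 0 means uniform orientations on [0, 90]. The closed
form of the resulting angle-to-tangent distribution (fold of 90° + wrapped
normal deviation) provides the analytic masses and medians the tests
compare against — an oracle independent of the rendering path. Suprabasal
and dermal nuclei are rounder, sparser and randomly oriented.
Intercellular gaps are dark ellipses rejection-placed inside the epidermis
(never overlapping nuclei) until the target area fraction is met, giving an
exact ground-truth mask; with abnormal intervals declared, the target
applies inside them and a separate background fraction (default 0.02)
outside, otherwise to the whole epidermis. Marker channels render diffuse
per-compartment intensities (membrane/cytoplasmic markers are diffuse —
staining physics is out of scope) plus, for nuclear markers, per-nucleus
Bernoulli positivity painted at a fixed positive intensity; abnormal
intervals can scale epidermal intensity and override positivity fractions.
The HES-like composite is a deterministic colour mapping of compartments
(background and gaps dark, tissue bright, nuclei intermediate), not a
physical stain model — downstream cohesion analysis only needs grayscale
contrast. One RNG stream per structural element, spawned from the spec
seed, keeps nucleus placement bit-stable when marker specs change; fixed
seed ⇒ bit-identical output.

What the generator does **not** emulate: real chromatin texture, stain
variability, out-of-focus blur, scanner artifacts, 3-D sectioning effects,
nuclear crowding beyond simple overlap, or keratinocyte infiltration
geometry. Passing tests therefore demonstrate correctness of the
measurement chain under known geometry and noise, not segmentation
robustness on real slides.

## Problem sizes and numerical choices

Default fixtures are 1600 × 400 px at 0.5 µm/px (800 µm of section);
polarity-recovery checks use 2134 px wide sections (~200 basal nuclei).
Cohort-level experiments use 700 × 170 px sections at 1 µm/px (~100 basal
nuclei, 10 sections per cohort; 500 px sections for the 200-replicate null
calibration) — sizes chosen so the complete simulation studies run in
minutes on one CPU while keeping per-section binomial noise well below the
effect sizes of interest. The two study-like conditions are fixed in
`pipeline.control_spec` (κ = 8, gap fraction 0.02) and
`pipeline.dysplastic_spec` (identical, plus a 400 µm abnormal interval with
uniform orientations and gap fraction 0.12); κ = 8 puts ~86% of basal
angles in [60°, 90°], matching the strongly perpendicular organisation of
healthy basal layers, and 2% background gap area is of the order of the
model system's background irregularity.

Tie-breaks and degenerate inputs: watershed plateau ties are resolved by
scan order, which the canonical-frame rotation makes orientation-stable;
blank rasters yield empty nucleus lists (not errors); empty ROIs and empty
regions are flagged rather than raised; a zero-DAPI mask under DAPI
normalization is an error. The Mann–Whitney "large-n" oracle comparison
uses n = 60 per group, where the continuity-corrected normal approximation
is accurate to within Monte-Carlo noise of a 10⁵-permutation estimate.

## Known limitations

- The JDE trace assumes the junction is single-valued per column after
  canonical orientation; strongly re-entrant junctions (true keratinocyte
  infiltration fronts) would need a contour-based trace.
- Cohesion scores are arbitrary units; only contrasts within an experiment
  are meaningful, and absolute values depend on k, the noise filter and the
  space polarity convention.
- The positive-cell threshold is an automated surrogate for manual
  counting; its mean + 3·SD rule is a convention and is configuration-
  exposed.
- Pooling regions across sections into cohort samples pseudo-replicates;
  the per-xenograft aggregation option exists for stricter inference.
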