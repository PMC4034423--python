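# Methods

## Data model

A dataset is a collection of blastomeres, each a closed, consistently wound
triangle mesh in physical micrometre coordinates, indexed by a stable cell id
and an integer frame index. Frames need not be uniformly spaced in time —
segmentation of time-lapse data is typically sparse, concentrating on frames
with divisions or substantial movement — so a frame→minutes map carries the
clock (15 min per nominal frame by default) and all per-frame statistics are
reported against frame indices, never against assumed uniform time.

Mesh invariants are enforced at load: watertightness (every edge shared by
exactly two faces), no degenerate faces, and outward winding (positive signed
volume). A consistently inward-wound mesh is auto-reoriented with a logged
warning; anything else is a hard, named error. Areas, enclosed volumes and
volume centroids are divergence-theorem quantities on the triangulation
(`trimesh`); the test suite checks them independently against closed forms
(cube, icosphere limits) and voxel-counting oracles with analytic insideness
(L-prism).

**Embryo centre.** The centre of the embryo at a frame is the volume-weighted
mean of per-cell volume centroids. This was a genuinely open choice (an
all-vertex mean or an unweighted centroid mean would also be defensible); the
volume-weighted form is robust to unequal cell sizes and reduces to the
unweighted mean for equal cells. It is configurable (`centre_mode`:
`volume` / `equal` / `vertex`).

## Surface exposure by normal-ray occlusion

For each face of a target cell, one ray is fired from the face centroid,
offset by ε = 10⁻⁶ × the frame's bounding-box diagonal along the outward
normal, in the direction of that normal. The face is external iff the ray
escapes to infinity without intersecting any other triangle of the frame.
Choices worth stating:

- **One ray per face, from the centroid.** Firing several rays per face or
  using vertices would be defensible; centroids are the cheapest unbiased
  choice and the subdivision-convergence test shows exposure moves < 2%
  between consecutive icosphere subdivision levels for fixed configurations.
- **Self-occlusion counts.** Rays may hit other faces of the same cell
  (concave cells shade themselves); only the origin face is excluded, and the
  ε offset makes the exclusion numerically safe.
- **Edge-inclusive intersection.** The Möller–Trumbore test uses inclusive
  barycentric bounds (tolerance 10⁻¹⁰), so a ray meeting a shared edge or
  vertex of a watertight mesh still registers a hit; rays cannot slip through
  seams between triangles.
- **Acceleration.** Triangles are grouped per cell under axis-aligned
  bounding boxes: a ray is tested against a cell's triangle block only if it
  intersects the cell's box (conservative slab test; false positives allowed,
  misses impossible). Correctness is established by exact label equality with
  a brute-force all-pairs oracle — an independent plane-intersection plus
  sign-test implementation in the test suite — over 100 random multi-cell
  frames.

Exposure = Σ area(external faces) / Σ area(all faces). It is exactly
invariant under global rigid motion and uniform scaling, equals 1 for a lone
cell and 0 for a fully enclosed one, and never increases when occluders are
added.

## Division angles and the isotropic null

θ is the folded angle (∈ [0°, 90°]) between the mother's radial axis (mother
centroid → embryo centre, frame before division) and the daughter–daughter
axis (frame after). 0° is a tangential cleavage (asymmetric: inner + outer
daughter), 90° a radial cleavage (symmetric). The frame after is used as
recorded even when the segmentation gap exceeds one nominal interval; a
warning is logged in that case.

Under uniformly random division-axis orientation, θ has density sin θ and CDF
1 − cos θ. The goodness-of-fit test is Pearson χ² of observed counts against
expected counts n·(cos a − cos b) per bin [a, b], df = bins − 1, upper-tail
p. Defaults: nine 10° bins. No Yates correction and no pooling of
low-expectation bins is applied; at n ≈ 24–96 divisions the near-0° bins have
small expectations (the 0–10° bin expects n·0.0152), so p-values depend on
the binning — the bin edges are configurable everywhere and reported
alongside results. Monte-Carlo calibration (10,000 replicates at n = 48 and
n = 96, six 15° bins) puts the type-I error at ≈ 0.047–0.050 at nominal
α = 0.05.

## Lineage, fate history, movement

Divisions are supplied as an explicit table (cell_id, parent_id, frame_first,
frame_last); the package validates binary divisions, absence of cycles and
orphans, and that a mother never coexists with her daughters. A cell absent
from an unsegmented intermediate frame keeps its identity across the gap. A
detection helper exists (mother id disappears, two new ids appear) but is
explicitly a starting point for review: volume conservation alone cannot pair
simultaneous same-volume daughters, so candidate pairs are ranked by the
distance of their volume-weighted midpoint from the vanished mother's centre
(mass is conserved through cleavage) and then by volume error.

Volume validation passes when |V(d₁) + V(d₂) − V(m)| ≤ tol × V(m), default
tol = 0.2 for segmented data (manual contours lose or gain a little volume);
the synthetic generator conserves volume exactly and passes at tol = 0.05.

The fate-history plot places each 32-cell-stage cell at signed coordinates:
|x| = grandmother's division angle (8→16 round), |y| = mother's (16→32
round); the sign is + when the relevant cell was the outer daughter (farther
centroid from the embryo centre in the frame after division). Exact radius
ties are broken toward the lexicographically smaller id with a logged
warning. Sisters therefore mirror exactly about the x-axis.

"Inside cell" means exposure below a threshold. The threshold is a genuine
free parameter — *negligible* exposure has no canonical number — so the
default is 0.01, it is configurable everywhere, and a sensitivity table
(count vs threshold) is provided because stage-level inside-cell counts
depend on it. "Early" / "late" 16-cell stage = first frame with 16 cells /
last frame before the 17th appears. "Exposure at formation" is measured at
the first frame in which a cell exists.

## Polarity

Voxels within `shell_um` (default 1.0 µm, about the width of a membrane
signal at typical confocal resolution) of a cell's surface are partitioned by
whether their nearest face is external (apical) or internal (basolateral);
the polarity measure is mean apical / mean basolateral intensity. Ratios are
flagged undefined — never coerced to zero — when a domain is empty (lone
cells have no basolateral domain, enclosed cells no apical one). The ratio is
invariant to intensity gain but not to an additive offset; no background
subtraction is applied by default. Dividing vs nondividing cells are compared
with the classical equal-variance Student unpaired t-test (Welch available);
mesh↔voxel registration is explicit (origin + spacing in the manifest), never
estimated.

## The synthetic digital-embryo generator

The generator emulates the study conditions the analysis assumes: embryos
followed from 8 to 32 cells at 15-minute nominal frames, near-spherical
compacted blastomeres (~13 µm radius at the 8-cell stage inside a 28 µm
envelope), two division waves (each split into two staggered sub-waves, as in
time-lapse recordings), exact equal-volume splits, post-division "jostling"
(Gaussian position noise, default SD 1 µm, followed by relaxation), optional
inward movement of outside cells at the 16-cell stage, and a positional fate
rule at the final frame (exposure < 0.01 ⇒ ICM).

Mechanics: rigid spheres relaxed by pairwise half-overlap repulsion, a weak
centripetal compaction drift (0.1 µm per iteration, 40 iterations per frame)
and a hard envelope clamp. Real blastomeres deform; rigid spheres suffice for
the exposure/angle/fate logic and keep every ground-truth quantity exact.
Two consequences are deliberate:

- **Frozen measurement frames.** Daughters appear exactly at
  mother ± r_d·u along the sampled axis u and nothing else moves in that
  frame, so the true angle is recoverable from the meshes to numerical
  precision (the measured-vs-true maximum error is ~10⁻¹⁰ degrees);
  relaxation resumes the following frame.
- **Interior capacity.** At the 16-cell stage the interior of the embryo has
  room for only about two blastomeres of this size, so internalisation
  saturates: of the outside cells selected at the configured rate, at most
  two are actually pulled inward. This keeps the dose response (rate →
  late-16-cell inside count) strictly monotone over rates up to ~0.4 and is
  the physically sensible behaviour — an embryo cannot internalise half its
  cells at once.

Angle policies: `isotropic` (θ = arccos U, azimuth uniform — the sin θ law),
`fixed` θ, or `mixture` (with probability f, θ is sin-weighted on [0°, 30°);
otherwise sin-weighted on [30°, 90°]), so the configured asymmetric fraction
f equals the expected fraction of divisions with θ < 30°. An optional
history rule (`te_restriction_threshold`) additionally forces TE on cells
whose mother's exposure at formation exceeded the threshold; it is off by
default, so in default runs ICM cells *can* descend from high-exposure
mothers via internalisation.

`make_enclosed_blastocyst(k)` constructs a blastocyst with exactly k fully
enclosed cells and *proves* the enclosure geometrically at build time: it
verifies (on a 16,384-direction grid, with a ≥ 0.5 µm margin) that the whole
mid-shell sphere is covered by the inscribed balls of the outer-cell meshes,
so every ray leaving an inner cell must pass through — and, with the
edge-inclusive intersection test, hit — an outer mesh. The outer cells
overlap heavily by construction; this is occlusion geometry, not physical
packing.

The voxel renderer paints a membrane shell (default 2 µm thick) around each
mesh; apical-adjacent voxels get `apical_enrichment` × the basolateral
intensity, per cell when a mapping is supplied (dividing cells are rendered
with reduced enrichment that way). Where shells overlap, basolateral paint
wins — contact zones are basolateral membrane for both partners. Gaussian
noise is added last. The residual ~3% downward bias in recovered enrichment
(1.93 measured for a rendered factor 2) comes from apical voxels near contact
rims falling inside a neighbour's basolateral shell; it is a faithful model
of domain-boundary cross-talk, not an estimator defect.

All randomness flows from one `numpy` generator seeded by the config; a fixed
seed reproduces the dataset bit for bit.

### What the synthetic data does and does not show

The generator reproduces the *structure* real data would have — watertight
per-cell meshes with occlusion, volume-conserving binary divisions, staggered
waves, movement coupled to divisions, inside cells arising both from
asymmetric division and from internalisation — so green tests demonstrate
that the measurement pipeline is correct and calibrated. They do not
demonstrate anything about real embryos: sphere packing has no cortical
tension or adhesion, exposures at the 32-cell stage are nearly bimodal
(enclosed vs ~0.4) rather than continuous, cell shapes never deform, and fate
is positional by construction. Quantities like mean inside-cell counts per
stage are properties of these synthetic conditions, not biological estimates.

## I/O conventions

One ASCII OBJ (or binary PLY) mesh per cell per frame, listed in a JSON
manifest that declares units (µm, enforced), the frame→minutes map, optional
per-cell dividing flags and an optional TIFF membrane volume with spacing and
origin. OBJ is written with 12 significant digits and PLY with float64
vertices (the stock float32 PLY would perturb exposures at the 10⁻⁹ level),
so write→read round trips preserve all downstream statistics to better than
10⁻⁹. CSV tables are comma-separated UTF-8 with header rows; angles in
degrees, exposures dimensionless. All CLI outputs are re-readable by the
package and byte-identical across re-runs on identical inputs.

## Problem sizes used in tests and the acceptance script

Icosphere subdivision 2 (320 faces/cell) is the default mesh resolution —
the subdivision-convergence test justifies it for exposure work; the
acceptance script analyses three full embryos end to end, runs the isotropy
calibration at 10,000 replicates, recovers the mixture fraction from 200
divisions, the internalisation dose response over 5 rates × 10 seeds, and
the polarity power study over 25 noise seeds, completing in about a minute
on one CPU.

## Known limitations

- Exposure is resolution-dependent near tangencies: a face whose ray grazes
  a neighbour flips label under refinement (bounded by the convergence
  check, but present).
- The χ² isotropy test's p-value depends on binning; with the default nine
  10° bins and n < 50 the extreme-asymmetric bins have expectations < 1.
- The polarity ratio has the ~3% contact-rim bias described above, and is
  not invariant to additive intensity offsets.
- The division-detection helper assumes volume conservation and centroid
  continuity; it will mis-pair exotic cases (e.g. simultaneous neighbouring
  divisions with strongly unequal daughter volumes) and is meant for review,
  not trust.
- The generator's fate rule is purely positional unless the optional history
  restriction is enabled; it does not model Yap/Tead4 signalling, apoptosis,
  fusion, or the 64-cell epiblast/primitive-endoderm split.
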