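# Methods

This note documents the operational definitions, parameters and design
choices behind the package, and what the synthetic validation does and
does not show about real sections.

## Inputs and conventions

A section is a pair of aligned binary rasters — mineralized bone and
hyaline articular cartilage — with an isotropic calibration
(`mm_per_pixel`, always user-supplied; scan resolution is acquisition
metadata, never a default).  Geometry is computed on the pixel grid
(origin top-left, x rightward, y downward, 0-based; pixel (i, j) has its
centre at (x = j, y = i)) and converted to mm only at reporting.
Sections are assumed mounted proximal-side up; `medial_side` records
which image side is anatomically medial, because frontal sections may
be mounted mirrored.  Inputs are pre-segmented masks: interactive
stain-based segmentation is out of scope (a naive grayscale threshold
helper exists as plumbing only).

## Landmark system

* **Line a** — humeral long axis.  Principal second-moment axis of the
  most distal `shaft_fraction` (default 0.30) of the filled periosteal
  envelope, oriented distal→proximal, computed in two passes: the first
  band is cut by image rows, the second perpendicular to the first-pass
  axis.  The second pass removes the bias a row-wise cutoff introduces
  on tilted shafts (a 200×40 px rectangle rotated 30° is recovered
  within 0.5°).  A manual two-point override takes precedence.
* **Line b** — segment between the annotated cranial and caudal
  cartilage ends; its midpoint is the head centre used for all
  articular rays.  Annotation endpoints must lie within 2 px of the
  cartilage mask.
* **Line c** — perpendicular to *a* through the caudal end of *b*,
  directed medial→lateral.
* **Line d** — parallel to *a*, tangent to the medial periosteal
  contour within the distal third of the section; tangency is the
  extreme medial envelope pixel, ties broken by the more distal point.
* **Line e** — from the midpoint of *b*, perpendicular to *b*, towards
  the joint surface, ending at the inner surface of the subchondral
  plate.  The plate is located by a cartilage-anchored walk: find the
  outermost cartilage run on the ray, walk inward from its deep edge,
  and accept the first bone run of length ≥ `plate_min_run` (default
  3 px) as the plate; line *e* ends at the midpoint between that run's
  last bone sample and the first marrow sample beneath it.  Anchoring
  at the cartilage is essential: trabeculae are wider than any sensible
  minimum run, so a blind walk outward from the head centre would stop
  at the first trabecula.
* **s1** = medial segment of line *c* (caudal cartilage end → line *d*)
  divided by 3; **s2** = |line *e*| / 3; **head height** = distance
  along *a* from line *c* to the most proximal cartilage pixel.

Construction invariants (c ⊥ a and d ∥ a to 1e−9 on unit vectors; e ⊥ b
through the midpoint of b within 0.5 px; 3·s1 and 3·s2 reproduce their
parent segments within 0.5 px) are asserted by `LandmarkSet.validate`
and exercised over randomized synthetic sections in the tests.

## Region partition

The plate inner surface is traced per angle with the same
cartilage-anchored walk on a 1° fan from the head centre (missing rays
are interpolated from neighbours).  Regions:

* `h` — fan polygon of the per-angle inner-plate radius minus a margin
  (`margin_mm`, default 0.06 mm), closed along line *b*;
* `inner` — the same fan at radius − *s2*; `subchondral` — the crescent
  between them, built on the identical vertex chains so the two parts
  tile `h` pixel-exactly up to a handful of chord-corner pixels;
* `sc1`, `sc2` — bands of width *s2* parallel to and distal of *b*,
  clipped to the periosteal envelope eroded by the locally measured
  lamella thickness (runs measured on stained tissue from the marrow
  interior outward) plus `erosion_margin_mm` (default 0.05 mm) — the
  cortical lamellae at both ends are thereby excluded;
* `m1`, `m2` — strips of width *s1* distal of line *c* (m1
  medial-most), extending 2·*s1* distally (`m_length_factor`,
  configurable: the source scheme fixes only the strips' long
  boundaries), clipped to the envelope eroded by the medial cortical
  thickness.

Margins and erosions are physical lengths (mm), so the partition is
stable under resampling of the same section (super-sampling 2× moves
BV/TV by < 0.5 pp).

Two resolutions of under-determined geometry, made once and applied
identically to ground truth and measurement:

* The oblique subcapital bands geometrically overlap the metaphyseal
  strips near the calcar (line *b* is tilted ~45° against line *c*).
  The strips take precedence; the bands are clipped around them.
  Subtracting the bands from the strips instead would leave `m1` almost
  empty.
* An "articular cap" region (everything inside the outer cartilage
  surface per fan angle, plus 3 px) is subtracted from bands and strips
  so that none of them reaches under the joint surface where plate and
  calcar cortex meet.

## Measurement operators

* **BV/TV** — 100 × bone pixels / total pixels inside the region
  polygon, pixel-centre point-in-polygon rule, no partial-pixel
  weighting.  This matches counting-based histomorphometry and is
  exactly testable against direct enumeration.  Additivity over the
  subchondral/inner split of `h` holds to the boundary-pixel level
  (< 0.05 pp).
* **Plate thickness** — along each of the 19 rays (10° steps from the
  head centre, endpoints of the semicircle included), the outermost
  cartilage run marks the deep cartilage edge; walking back inward, the
  plate ends at the first unstained sample.  Thickness = distance
  between the two interfaces × calibration.  A ray that crosses no
  cartilage yields an explicit missing value (excluded from statistics,
  never zero-filled).  The two end rays of the semicircle run along the
  cartilage margin itself and would graze it, so they are always
  measured 0.5° inside the semicircle; any ray that still finds no
  cartilage is retried nudged up to 1.5° inward before being declared
  missing.
* **Cortical thickness** — at each of 9 levels per side (spacing =
  head height / 8 along line *a*, starting at line *c*): the surface
  point is the outermost envelope crossing along the perpendicular of
  *a*; the local contour direction is estimated from surface points
  ±3 px along the axis; thickness is the first contiguous bone run
  along the inward normal, skipping leading runs < 3 px (grazing
  slivers at tissue junctions), with a horizontal-chord fallback when
  the normal is undefined.  Sampling steps are 0.25 px with interface
  positions taken at sample midpoints.

## Statistics

* WHO T-score bands: osteoporotic T ≤ −2.5, normal T ≥ −1.0, osteopenia
  between; osteopenic donors are excluded from two-group comparisons
  with a logged warning.
* Shapiro–Wilk gate per variable per group at `alpha_gate` = 0.05; a
  zero-variance sample cannot be assessed and is routed nonparametric.
  One failing variable routes its whole comparison family to the
  nonparametric path.
* Within-group regional families (head/subcapital, head/metaphysis,
  subchondral/inner): repeated-measures parametric path (pairwise
  paired t contrasts; an AnovaRM omnibus is available, without
  sphericity correction) or pairwise Wilcoxon signed-rank.  The
  signed-rank null is exact for n ≤ 25 (dynamic programming over sign
  assignments; midranks doubled to an integer grid handle ties; zero
  differences dropped) and a continuity-corrected normal approximation
  above; the exact path is verified against exhaustive 2^n enumeration.
* Between-group comparisons: Welch (unequal-variance) t-test on the
  parametric path — small, possibly unequal groups — otherwise
  Mann–Whitney rank-sum.  (An independent-samples problem cannot be
  addressed by a related-samples signed-rank test; the rank-sum test is
  the coherent nonparametric counterpart.)
* Bonferroni within each family: adjusted p = min(1, m·p) with m = the
  number of pairs in the family (3 for the two three-region BV/TV
  families, 2 where each region is tested once between groups, 19 for
  the plate-angle family, 9 per cortical side).  Correction is never
  pooled across families.
* α = 0.05 throughout, two-sided, configurable.
* Calibration: under a null simulation (both groups N(μ, σ), n = 6 + 6,
  2,000 replicates) the gated pipeline's type-I error stays within
  [0.03, 0.07].  Note a structural small-sample fact: with n = 6 the
  signed-rank path's smallest two-sided p is 2/64, so after Bonferroni
  over 3 pairs the nonparametric within-group path can never reach
  significance — within-group findings at this n are intrinsically
  conditional on passing the normality gate.

## Synthetic sections

The generator draws an idealized frontal proximal humerus: a circular
head (default radius 22 mm) whose articular semicircle is tilted 45°
towards medial-proximal, carrying a 1.2 mm cartilage band and a
subchondral plate with an angular thickness profile (default 0.85–1.0
mm); a metaphysis whose medial contour leaves the articular margin at
an oblique take-off and straightens into a near-vertical calcar before
tapering to an 18 mm shaft whose axis is offset 8 mm lateral of the
head centre; medial and lateral cortical walls with prescribed
thickness-by-level profiles (default 0.85→3.5 mm and 0.8→3.0 mm over
one head height), drawn by thresholding the Euclidean distance
transform at the thickness of the nearest boundary point so that the
drawn wall is the prescribed *normal* thickness.  Defaults make the
plate thickness at the caudal end equal the medial cortical thickness
at level 0: the two structures meet there, so the compact bone at that
junction must have a single well-defined thickness.

The trabecular interior is filled by a seeded dead-leaves process:
oriented elongated ellipses (width ~ N(0.15, 0.03) mm, aspect 3–8)
drawn independently per ground-truth region, clipped to the region
stencil, until each region's bone-area fraction is within 0.5 pp of its
target; near the target, small round leaves sized to the remaining
deficit avoid overshoot.  Achieved fractions are recorded by direct
pixel counting, so the declared ground truth is self-consistent by
construction.  A 2 px marrow collar separates trabeculae from plate and
cortex so thickness ground truth is unambiguous.

A cohort draws `n_per_group` donors per group (default 6 + 6, mirroring
a typical donor study): truncated-normal T-scores (normal-like in
[−0.9, 1.6], osteoporotic-like in [−6.5, −2.7]), per-donor jitter as a
shared logit shift (sd 0.06) plus independent per-region logit noise
(sd 0.05) on the targets, ±4 % head-radius scaling, and one shared
compact-bone scale factor (±5 %) on plate and cortex drawn identically
in both groups — the plate and cortex group-null is thereby preserved
by design.  Osteoporotic-like targets are the normal template times a
per-region multiplier (strongest loss in m1/sc1, mildest under the
plate); the normal template keeps head, metaphysis and the
subchondral/inner split nearly level, so that head-vs-metaphysis and
subchondral-vs-inner differences emerge only in the osteoporotic-like
group, while the subcapital depression (sc1 < sc2 < h) is present in
both.

**What the phantom does not emulate:** trabecular connectivity and
plate-merging trabeculae (the collar removes them), anisotropic
trabecular alignment along stress trajectories, segmentation noise and
staining artefacts, out-of-plane anatomy (a single 2D section), and
cortical porosity.  Passing the recovery battery therefore shows that
the geometric and measurement chain is correct and well-conditioned on
clean masks — not that segmentation of real stained sections is solved.

## Problem sizes and reproducibility

The test suite and the acceptance script run the recovery battery on 50
sections at the default calibration of 0.025 mm/px (≈ 4000 × 1900 px
rasters) and the pattern study on three independent 6 + 6 cohorts; unit
tests use a scaled section (10 mm head at 0.05 mm/px) that preserves
every structure.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence`; regenerating with the same spec is
bit-identical, and pipeline results files embed a hash of the full
configuration.

Because ~35 hypothesis tests at n = 6 enter the qualitative pattern
checks, single-cohort outcomes are stochastic (the normality gate alone
fails one variable in a three-column family on ~14 % of cohorts); the
pattern battery therefore requires the patterns in at least 2 of 3
cohorts rather than in every seed.

## Known limitations

* Cortical thickness below ~3 px (0.075 mm at default calibration) is
  treated as absent by the sliver filter.
* The medial level-0 cortical site sits at the plate/calcar junction;
  on real bone its value depends on how the observer resolves that
  junction.
* Regions depend on the annotated cartilage ends; a few px of
  annotation error shift line *c* and the strip origins accordingly
  (Jaccard against ground truth stays ≥ 0.90 under the generator's
  jitter, but gross annotation errors are not detected).
* The repeated-measures omnibus applies no sphericity correction by
  default.
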