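# Methods

This note documents the models and procedures `lesionqol` implements, the
defaults it chooses where the underlying study design leaves the choice
open, and what the synthetic validation does and does not establish.

## Questionnaire scoring

EORTC QLQ-C30 (items 1–30) and QLQ-BN20 (items 31–50) responses are scored
per scale as the mean of the answered member items (the *raw score*),
provided at least half of the items were answered (exactly half counts;
this is the standard "half-rule").  The raw score is rescaled linearly to
0–100:

* functional scales: `S = 100 · (1 − (raw − 1)/r)` — higher is better;
* symptom scales and the global scale: `S = 100 · (raw − 1)/r` — higher is
  a worse burden (global: higher is better health, same formula because the
  7-point global items are coded 1 = very poor … 7 = excellent).

`r` is the item range: 3 for the 4-point items, 6 for the two 7-point
global items.  The item-to-scale composition ships as a replaceable data
file (`src/lesionqol/data/qlq_scales.tsv`), so the engine is agnostic to
the scoring-manual version; the shipped table follows the standard C30 v3 /
BN20 composition.  BN20 scales are scored in the symptom direction (higher
= more problems), as the BN20 manual defines them, even for the four
"functional" BN20 scales.  Scores are not rounded; the reporting layer
formats them.

## Lesion mapping

Four binary lesion masks are tracked per subject: resection cavity, T1-CE
enhancing lesion, T2/FLAIR hyperintensity and FET-PET positive volume.
PET positivity is `uptake / background_mean > 1.6` where the background
mean is the arithmetic mean inside a user-supplied healthy-brain mask; no
automatic background construction is attempted, because background
definitions vary between sites and scanners.

All volumes must share one grid (shape and affine); the module refuses to
resample.  Overlap of a lesion with an atlas region is the voxel count of
the intersection times the voxel volume, reported both in mL and as a
fraction of the region volume.  The screens use mL by default; because
Kendall correlation depends only on ranks, the choice is immaterial for a
fixed region and is exposed only for completeness of the tables.  For each
subject and lesion type the table also reports the lesion volume falling on
atlas background, so that atlas overlap plus off-atlas volume always
reconstructs the total — a conservation property the tests enforce.

Tumour laterality is the sign of the union-lesion centre of mass along the
first world axis (negative = left); an exactly-zero centre falls to the
side with more lesion voxels, ties to the left.  This is a computed
convention — radiological readings may differ for genuinely bilateral
lesions, which the pipeline flags rather than silently classifies when the
union mask is empty.

## Connectivity

Node series are band-pass filtered to 0.008–0.09 Hz with a frequency-domain
filter: unit gain in the band, half-cosine roll-off of width `low/2` below
and 0.01 Hz above, zero at DC (mean removal).  Pearson correlations between
filtered node series are clipped at ±(1 − 1e−7) before the Fisher transform
so z is always finite; constant nodes are excluded with a warning.
Within-network connectivity of a node is the mean z to the other nodes of
its network pool.  Pools are hemisphere-specific by default (the left and
right halves of a network are separate), since lesion effects of interest
are lateralized; a `bilateral` switch pools both hemispheres.  Per-node
(rather than per-pair) averaging is used because the downstream screen
correlates *node-level* connectivity with the HRQoL scales.

## Statistical layer

* **Kendall τ-b** with the tie-corrected denominator
  `(C − D)/√((n₀−n₁)(n₀−n₂))`; two-sided p from the tie-corrected normal
  approximation (exact enumeration for tie-free samples with n ≤ 10).
  Implemented over `scipy.stats` — the reference implementation for this
  statistic — with pairwise-complete missing handling and explicit flagging
  of constant inputs; the test suite checks the estimate against an
  independent all-pairs enumeration to 1e−12.
* **Mann–Whitney U**, two-sided, average ranks for ties; exact for small
  tie-free samples, tie-corrected normal approximation otherwise.
* **Pearson χ²** on 2×2 tables, df = 1, without continuity correction.
  This choice reproduces, at printed precision, the published two-sided
  p-values of seven left-vs-right cohort characteristics used as anchors in
  the acceptance checks (e.g. aphasia 15/50 vs 2/54 → p = 0.002).
* **Effect grading**: Cohen's d with pooled SD, classes at |d| ≥
  0.2/0.5/0.8 (lower bounds inclusive); correlation classes at |r| ≥
  0.1/0.3/0.5; clinical importance of a 0–100 score difference at |Δ| < 5
  trivial, 5–10 minimal, 10–20 moderate, > 20 very much, with the 10- and
  20-point boundaries assigned upward.
* **Screens**: Kendall τ-b of every (lesion type × region) overlap against
  every scale at α = 0.001; Pearson r of every node's within-network
  connectivity against every scale at α = 0.01.  No multiplicity
  correction is applied — the screens are hypothesis-generating, and the
  stringent per-cell thresholds are the only stringency control.  Cells
  with a constant predictor (regions never touched by any lesion) are
  undefined and excluded from the significant list rather than reported as
  p = NaN hits.

A calibration note: for predictors that are mostly zeros (a region only a
handful of lesions reach), the tie-corrected normal approximation is
*conservative* in the extreme tail — direct simulation shows rejection
rates at p < 0.001 of roughly 0.0002–0.0005 for 5–20 % nonzero predictors,
approaching the nominal 0.001 only for dense ones.  The screen therefore
under-flags, never over-flags, sparse regions; pooled over a whole screen
the empirical null rate sits below 0.001.  This is a property of the rank
statistic under heavy ties, not of this implementation.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated.  Defaults mirror the study design the analysis targets: 121
subjects (56/121 right-sided), a 50×60×50 grid at 3 mm, 2 × 50 cortical
nodes in 7 networks, 2 × 24 tracts plus 5 midline structures, 300 time
points at TR = 2.2 s.

* **Atlas**: regions are boxes on a lattice consumed from the hemisphere
  centre outward, mirrored across the midplane; nodes are 12 mm cubes
  (≈ 1.7 mL), tracts elongated 9×24×9 mm boxes.  Geometry is deterministic,
  so every overlap has an exact enumerable value.
* **Lesions**: random axis-aligned ellipsoids with per-axis radius jitter
  (±30 %).  Mean radii — FLAIR 23 mm, cavity 13 mm, T1-CE 11 mm, FET
  15 mm — were chosen so simulated volumes land in the ranges reported for
  pretreated high-grade-glioma cohorts (FLAIR median ≈ 50 mL, cavity
  ≈ 10 mL, T1-CE ≈ 5 mL, FET ≈ 15 mL); absence probabilities (cavity 0.15,
  T1-CE 0.25, FET 0.48) mirror the fraction of patients without such
  lesions.  Cavity and T1-CE are concentric with and intersected into the
  FLAIR envelope (nesting); the FET centre is drawn inside the FLAIR
  ellipsoid so the two always intersect when both exist.
* **Time series**: a factor model.  Node i's signal is
  `√ρ_b·G + b_i·F_net(i) + e_i·E_i` with independent standard-normal
  factors; `b_i = √(ρ_w − ρ_b) · m_i` and `e_i` sets unit variance.  Intact
  nodes (`m_i = 1`) correlate at ρ_w within a (hemisphere-specific) network
  and ρ_b across networks; the coupling multiplier
  `m_i = max(floor, 1 − strength · FLAIR-fraction_i)` decays linearly in
  the node's lesion overlap, so a fully attenuated node falls to the
  between-network level.  The construction is positive semi-definite by
  design; parameters are validated (`0 ≤ ρ_b ≤ ρ_w < 1`) before sampling.
  The linear form is a modelling choice — only the direction (lesions
  reduce coupling) is empirically grounded.
* **Responses**: per subject and scale, a latent score
  `baseline + Σ slope·predictor + N(0, σ)` is clamped to [0,100], inverted
  through the scoring transform to a target item total, and distributed
  over the scale's items as near-equal integers (the half-way case rounds
  toward worse functioning).  Baselines: 85 (functional), 15 (symptom), 70
  (global); σ = 10 points for scales without a planted effect.  Scoring the
  responses recovers the latent score to within half a rescaled item step
  (`50/(r·k)` points for a k-item scale), which the tests assert for every
  scale.
* **Seeding**: one global seed feeds a `SeedSequence` keyed by (subject
  index, stage), so enlarging a cohort never changes existing subjects, and
  a sides-only draw (`simulate_sides`) matches the full imaging draw.

What the generator does *not* emulate: scanner physics, motion and
physiological noise, registration error, irregular lesion shapes,
infiltrative growth along tracts, non-Gaussian BOLD marginals, and
questionnaire response styles (acquiescence, item non-response patterns).
Passing tests therefore demonstrate that the pipeline recovers effects it
is pointed at and stays quiet under its own null — not that the effect
sizes or p-value maps of any real cohort are reproduced.

## Validation problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: planted-effect power over 10–20 cohorts of 120 subjects, null
calibration over 6–10 cohorts, laterality recovery over 20
questionnaire-only cohorts of 121 subjects, connectivity separation over
10 single-subject draws of 100 nodes × 300 time points.  These sizes give
the batch criteria (≥ 90 % detection rates) a comfortable margin at the
planted effect sizes while keeping a full run in minutes.

## Known limitations

* The toy atlas is geometric, not anatomical; region adjacency (and hence
  the spatial smearing of screen hits) is cruder than in a real
  parcellation.
* Laterality from the centre of mass can misclassify strongly bilateral
  disease; such subjects are rare under the generator (unilateral centres)
  but real cohorts need the flagged-subject path.
* The Kendall screen's p-values are conservative for rarely-touched
  regions (see the calibration note above); interpret absence of a hit in
  a sparse region accordingly.
* The band-pass filter is an idealized frequency-domain design; FIR/IIR
  implementations used by common fMRI toolboxes differ slightly at the band
  edges.
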