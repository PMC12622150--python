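# Methods

This note documents the models, algorithms and numerical choices behind
`nucleovol`, and what the synthetic phantoms do and do not establish about
real data.

## Phantom model

A plate is a set of conditions (control first), each with a fixed number
of wells, fields per well, and cells per field.  Per field:

* **Nuclei** are filled, axis-aligned ellipsoids.  A base radius is drawn
  from a truncated normal (default 3.5 ± 0.25 µm, truncation at ±2.5 sd),
  then multiplied by `f_volume^(1/3)` for the cell's condition.  Shape
  anisotropy multiplies the three semi-axes by independent U(0.8, 1.2)
  draws normalized to product 1, so anisotropy changes shape but never
  volume; true volume is exactly `4/3·π·rz·ry·rx`.  The resulting ~21 %
  volume CV emulates a cell-cycle-arrested (retinoic-acid differentiated)
  population, which shows less volume spread than cycling cultures.
* **Placement** is rejection sampling with a minimum in-plane centre
  spacing (default 8 µm) and a margin keeping every ellipsoid inside the
  stack; after a bounded number of attempts (default 10 000 per field)
  generation fails with an error naming the well and field.  A cheap
  packing-density screen rejects clearly infeasible designs up front.
  Spacing is enforced in-plane (not 3D) because z-stacks are shallow and
  in-plane separation is what 2D segmentation relies on.
* **Foci** per nucleus: a uniform integer count (default 1–4); radii
  truncated-normal (0.8 ± 0.1 µm) times `f_area^(1/2)`; centres uniform in
  the nucleus, shrunk so the focus sphere stays strictly inside, and
  laterally separated from sibling foci by the sum of radii + 0.6 µm so
  distinct foci never merge in 2D.  If a nucleus is too crowded, fewer
  foci are planted and the truth records what was actually planted.
* **Channels** carry a flat background plus additive per-compartment
  amplitudes (nucleus, focus, cytoplasmic shell).  Condition factors
  multiply focus amplitude, non-DAPI nuclear amplitude, or cytoplasmic
  amplitude; DAPI is only affected geometrically.  The default preset uses
  DAPI (background 10, nuclear 100) and a pure nucleolar marker channel
  ("nP-Tau": background 0, focus 150), so amplitude-recovery tests are
  background-free by construction.
* **Optics and noise**: isotropic Gaussian blur (default σ 0.2 µm, a
  conservative confocal scale at 0.3 µm pixels), then Poisson shot noise
  on the blurred signal (interpreted as photon counts) plus additive
  Gaussian read noise (sd 2).  Each component can be switched off, which
  the exact oracle tests rely on.  Ground truth is recorded before blur
  and noise.
* **Calibration** defaults to 0.3 µm xy / 1.0 µm z (a typical 40× water
  confocal sampling).  All randomness flows from per-(well, field)
  `SeedSequence` children of the design seed, so truth and rendering are
  bit-reproducible and independent of evaluation order.

Presets encode the reported per-condition effect magnitudes of the
underlying study (e.g. SH-SY5Y 1 h P301S: nuclear volume ×1.025, nucleolar
focus area ×1.10, nucleolar tau amplitude ×2.0) at its scale (6 wells and
≥ 2 000 cells per condition for SH-SY5Y presets; ≥ 1 000 for iPSC).  The
MAPT-4R / MAPT-total qPCR preset folds are package assumptions (the source
reports only a strong induction with P301S > S305N); all rRNA folds are
the reported values.

The qPCR generator plants Ct = baseline − log2(ratio) per gene and
condition with i.i.d. Gaussian noise per technical replicate; reference
genes are drift-free.  `samples_per_condition` (default 3) models
biological replicates so the ΔCt comparison has a sample to test.

**What the phantoms do not emulate**: real chromatin texture, uneven
illumination, spectral bleed-through, touching or mitotic nuclei,
apoptotic morphology, z-dependent attenuation, or motion.  Passing the
suite therefore demonstrates correctness of the measurement chain on
geometrically ideal objects under a linear-optics noise model, not
segmentation robustness on difficult real images.

## Segmentation (per slice)

Gaussian smoothing (default σ 1 px) → Otsu or fixed threshold → optional
hole fill → optional distance-transform watershed split → area and
mean-intensity gates → contiguous relabel (8-connectivity).  Gates and all
reported intensities use the raw image; smoothing shapes boundaries only.
An all-constant slice under Otsu returns an empty result; non-finite
pixels raise.  The proprietary high-content software this stage replaces
documents only that nuclei are selected by size and brightness criteria,
so all cut-offs here are implementation defaults, not literature values.

Focus detection runs per slice inside the nuclear masks: a white top-hat
(disk footprint, default radius ≈ 2.2× the expected focus radius) or LoG
response is thresholded at `min_prominence` (default a quarter of the
expected focus amplitude when derived from a design; otherwise Otsu of
the in-nucleus response).  Each candidate is refined to the connected
half-prominence support around its peak — measured areas are therefore
invariant to linear intensity scaling — then gated by area and by mean ≥
`brightness_factor` × the host nucleoplasmic median (nucleus minus all
candidates), a per-cell reference robust to staining variation.  Host
assignment is by majority pixel vote with a ≥ 50 % requirement.

## 3D linking

Components on consecutive (or gap-bridged, `max_z_gap`) sections are
matched by greedy global-minimum mutual-nearest in-plane centroid
distance (µm) under `max_link_dist_um`; unmatched components start new
objects; matching is one-to-one, so splits/merges open new tracks.  Ties
break by smaller distance, then larger 2D overlap (computed on bounding
boxes), then smaller slice label — the partition is deterministic and
label-order-independent except as a last resort.  Defaults: cap 2 µm,
gap 1, `min_slices` 2 for nuclei; cap 1 µm, gap 0, `min_slices` 1 for
foci.  Volumes satisfy `voxel_count · px² · z_step` exactly; intensity
integration is an exact voxel sum.  On well-separated convex objects the
partition equals 26-connected 3D component labelling, which the tests
verify on a 50-phantom suite (with gap 0 / min_slices 1, since gap
bridging intentionally differs from plain connectivity).

Cytoplasm is the set of voxels outside all nuclei within
`shell_width_um` (anisotropic Euclidean distance, default 1.5 µm) of a
nucleus; in the batched pipeline each shell voxel goes to its *nearest*
nucleus, so shells are disjoint from nuclei and from each other.  Focus →
nucleus registration is by centroid-voxel containment: a single
unambiguous rule matching disjoint nuclear masks.

## Pipelines and aggregation

The cyto-nuclear pipeline produces one record per retained 3D nucleus
with exact per-channel nuclear and cytoplasmic means/integrals; the foci
pipeline reuses the same segmentation and adds per-cell focus count, mean
2D focus area (px² and µm², the per-focus pixel-area convention used for
neuronal nucleoli), total
focus volume, and the nucleolar mean intensity, defined as the
area-weighted mean marker intensity over all member sections of assigned
foci (i.e. the mean over detected foci voxels).  Border-touching nuclei
are dropped by default (their volume is truncated); unassigned foci are
excluded from per-cell metrics.  Well summaries (mean/median/sd per
metric) are exactly recomputable from the records; wells under a minimum
cell count are flagged, never dropped.  Percent change is
`100·(mean_treated − mean_control)/mean_control`; `condition_ratio`
reports the ratio of condition means with a Monte-Carlo SE propagated
from between-well variation, the well being the independent experimental
unit.

### Known limitation: PSF size-coupling of the intensity metric

The support-voxel mean is not a pure amplitude estimator under blur: for
ball-like foci the half-prominence support mean increases with focus
radius relative to the PSF.  With the default optics (σ 0.2 µm on
0.8 µm foci) a co-injected 10 % area factor inflates a recovered
amplitude ratio by ≈ +0.8 % (forward-model prediction 2.016 for a true
2.0; the pipeline measures 2.002–2.015 across seeds).  The effect is
invisible at ≤ few-hundred-cell scale but resolvable at thousands of
cells per condition.  Alternative local estimators (fixed-radius central
disc, peak value, flux over measured area) couple more strongly or trade
the bias for noise-selection bias, and deconvolution is out of scope;
amplitude recovery is exact on zero-PSF phantoms, which the unit tests
check.  Interpret sub-percent intensity-ratio differences at very large n
with this in mind.

## Statistics

Shapiro–Wilk on each sample (n ≥ 3 required); if either p <
`alpha_normality` (0.05), the two-sided Mann–Whitney U test is used;
otherwise Levene's test (mean-centred) checks variance homogeneity, and a
rejection also falls back to Mann–Whitney (configurable to Welch's t);
otherwise the unpaired two-tailed t-test.  Mann–Whitney p-values are
exact when min(n₁, n₂) ≤ 8 with no ties (verified against full
enumeration), else the tie-corrected normal approximation with continuity
correction.  Bonferroni multiplies by the family size m (an explicit
argument — the source does not define the family; the natural choice is
the number of mutant-vs-control contrasts in a panel, i.e. 2 for the
SH-SY5Y model).  Significance labels use the printed convention with
inclusive boundaries.  Box-plot summaries use linear-interpolation
quartiles and 1.5×IQR whiskers.  Under a normal null the full gate keeps
the type-I error at the nominal 0.05 (calibrated over 2 000 replicates in
the acceptance suite).

## ΔΔCt

Technical replicates are averaged per (sample, gene) before ΔCt — the
standard Livak order; amplification efficiency is assumed exactly 2 (no
standard-curve correction, as none is reported).  ΔΔCt uses pooled
condition means by default; a per-sample variant (mean of per-sample
folds against the control mean) is available.  Statistics run on the
per-sample ΔCt values through the same gate as imaging metrics.  The
secondary reference gene (RPS27) is used only for concordance (|log2
fold₁ − log2 fold₂| ≤ 0.5 by default), never averaged with the primary
(ACTB).  With zero Ct noise the recovered fold equals the planted ratio
to machine precision.

## Problem sizes

The acceptance tests and `scripts/acceptance.py` run the SH-SY5Y presets
at 6 wells × 4 fields × 100 cells per condition (≈ 2 400 cells) on
16 × 512 × 512 stacks, and the iPSC presets at 50 cells per field
(≈ 1 200 cells); the oracle suites use 50 independent 12 × 160 × 160
phantoms with 5 nuclei each; ddCt Monte-Carlo uses 200 seeds; the gate
calibration 2 000 null replicates.  These sizes were chosen to match the
scale of the emulated experiments while keeping a full run in the
minutes range on one CPU.
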