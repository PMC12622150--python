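# nucleovol

3D cyto-nuclear and nucleolar-foci quantification for high-content
fluorescence z-stacks, with a synthetic phantom generator, plate-level
statistics, and ΔΔCt qPCR analysis.

## The problem

High-content screens of neuronal models expressing disease-associated
*MAPT* (tau) mutations read out small multiplicative changes — a few
percent of nuclear volume, ~10 % of nucleolar size, up to ~2-fold in
nucleolar marker intensity — from thousands of cells per condition.  The
analysis chain behind such numbers is rarely published as runnable code:
nuclei are segmented on every axial section of a confocal z-stack, the 2D
components are assembled into 3D nuclei by nearest-neighbour linking,
bright nucleolar foci (FBL, UBF, NPM, nucleolar tau) are detected inside
the nuclear masks and registered to their host nucleus, per-cell metrics
are aggregated per well, and conditions are compared with a Shapiro–Wilk
gated Mann–Whitney/t-test protocol with Bonferroni correction.  Transcript
changes are quantified in parallel by ΔΔCt qPCR against dual reference
genes.

`nucleovol` reimplements that chain as a tested library.  Because the raw
images of such studies are typically not deposited, it ships a phantom
generator that renders multi-channel z-stacks with *known* ground truth —
ellipsoidal nuclei, planted spherical foci, per-condition multiplicative
effect factors, Gaussian PSF blur and Poisson–Gaussian noise — so every
stage of the pipeline is verifiable against planted truth, and reported
effect sizes can be injected and recovered end to end.

## Core definitions

* 3D assembly: components on consecutive sections are matched by greedy
  mutual-nearest in-plane centroid distance (µm) under a cap, with optional
  z-gap bridging; `volume_µm³ = voxel_count · pixel_size_xy² · z_step`
  holds exactly, and on well-separated objects the partition equals
  26-connected 3D component labelling.
* Focus detection: white top-hat (or LoG) candidates, refined to their
  half-prominence support, gated by area and by mean ≥ k × the host
  nucleoplasmic median; each 3D focus is registered to the nucleus whose
  mask contains its centroid.
* ΔΔCt: ΔCt = Ct(target) − Ct(reference) per sample (technical replicates
  averaged first), ΔΔCt = mean ΔCt(condition) − mean ΔCt(control),
  fold = 2^(−ΔΔCt); tests run on ΔCt values; a secondary reference gene is
  used only for concordance validation.
* Comparisons: Mann–Whitney U (exact for min n ≤ 8 without ties) when
  Shapiro–Wilk rejects normality or Levene rejects variance homogeneity,
  otherwise an unpaired two-tailed t-test; Bonferroni adjustment by the
  family size m; labels ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 /
  0.0001 (inclusive).

## Worked example

Simulate a two-condition plate at study scale (6 wells × 4 fields × 100
cells per condition; a few minutes) with a 2× nucleolar tau amplitude
effect, quantify it, and compare conditions:

```sh
nucleovol simulate --preset SH-SY5Y-1h/P301S --out plate --seed 5
nucleovol run --stacks plate --layout plate/plate_layout.csv --out results
nucleovol compare --cells results/cells.csv --layout plate/plate_layout.csv \
    --metric nucleolar_mean_intensity --control EV --family-size 2 \
    --out results/comparison.csv
```

The comparison prints:

```
nucleolar_mean_intensity P301S vs EV: +101.01% mann_whitney_u p_adj=0 ****
```

meaning the P301S wells show a ~101 % higher mean nucleolar marker
intensity than the empty-vector control (the preset injects a 2.0×
amplitude factor), significant by a two-sided Mann–Whitney U test after
Bonferroni correction.  The same library API is available in Python:

```python
import dataclasses
from nucleovol import study_presets, quantify_phantom_plate, condition_ratio

design = dataclasses.replace(study_presets("SH-SY5Y-1h", "P301S"), seed=1)
cells = quantify_phantom_plate(design)          # per-cell DataFrame
ratio, se = condition_ratio(cells, "nuclear_volume_um3", "EV", "P301S")
print(f"nuclear volume ratio {ratio:.4f} ± {se:.4f}")   # ≈ 1.031 ± 0.006
```

which recovers the injected 1.025 nuclear-volume factor within its
Monte-Carlo error from ~2 400 cells per condition.

qPCR analysis of a replicate-level Ct table:

```sh
nucleovol qpcr --ct ct.csv --target 45S --ref ACTB --ref2 RPS27 \
    --control EV --out folds.csv
# 45S P301S vs EV: fold 1.531 (p=0.0003034)
```

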