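# Methods

## The score

The AgeScore is a categorical sum over a marker panel. For each marker
*m* and timepoint *t*, the per-well summary values of the treated arm are
compared with the control arm; the marker's rating is

    r(m, t) = 1  if p(m, t) < α  and  sign(mean_treated − mean_control)
              matches the direction expected with age,
    r(m, t) = 0  otherwise,

with α = 0.05 by default. Primary and antagonistic ratings are summed
separately and their total is the full score. Because the score is a sum
of binarized test outcomes — not a continuous measurement with replicate
scatter — no dispersion is attached to it, and no uncertainty is
propagated from the underlying tests onto the score.

Two deliberate properties of the rating rule:

* **Direction gate.** A significant change in the *wrong* direction
  (e.g. p16 falling with treatment) scores 0 and is annotated in the
  calls table. Under the null this makes the rating strictly more
  conservative than the test's α: a null marker must be both falsely
  significant and, by a coin flip, in the expected direction.
* **No cross-marker correction.** Each marker is rated independently at
  α; the panel is a fixed battery, not a discovery screen, and the score
  is designed to be comparable across studies that use the same panel.

## Statistical engines

Wells are the biological replicates: per-cell readouts are averaged per
well first, and technical replicates (qPCR duplicates, ELISA duplicates,
telomere triplicates) are averaged before any testing, so they never
inflate n.

* `t_test` — two-sided Welch (unequal-variance) t-test per timepoint.
  Welch is used rather than the pooled-variance form because arm
  variances routinely differ when an effect also scales the noise; with
  equal variances the two coincide asymptotically. If both arms are
  constant and equal the p-value is defined as 1 (direction `none`).
* `anova1_tukey` — one-way ANOVA across all condition groups within a
  timepoint; the reported p is the Tukey-HSD-adjusted p of the
  treated-vs-control pair. Intended for multi-arm single-timepoint
  designs (e.g. senolytic treatment arms).
* `anova2_sidak` — the default for the 3/7/14-day marker panels: a
  two-way condition × timepoint layout. The per-timepoint contrast of
  treated vs control uses the pooled within-cell residual variance of
  the whole design (df = N − #cells), and its p-value is Sidak-adjusted
  for the number of timepoints, p_adj = 1 − (1 − p)^T. This controls
  the family-wise error of the per-marker timepoint family at α; the
  per-contrast adjusted rate is therefore ≈ α/T by construction.

Calibration is verified by simulation at the per-well level (1000 null
data sets, 6 wells/arm): the t-test's per-comparison type-I rate and the
Sidak path's family-wise rate both sit in [0.03, 0.07] at α = 0.05, and
power for a +3 SD per-well shift exceeds 95%.

## Image measurements

* **Segmentation.** Otsu threshold on a σ = 1 px Gaussian-smoothed
  nucleus channel, hole filling, removal of objects < 50 px and of
  anything touching the image border. Label 0 is background; indexing is
  0-based, row-major, origin top-left.
* **Focus / punctum counting.** A spot is a 4-connected component of
  pixels inside the inclusive intensity window (default 20–200) with
  area ≥ the minimum size (default 5 px), restricted to the compartment
  (nucleus for DNA-damage foci, cytoplasm for stress granules and
  phagocytosed particles). 4-connectivity splits near-touching spots
  conservatively. A nucleus whose whole interior falls inside the window
  counts as one spanning component — a documented pathological case of
  the window rule. Window and size are configuration, not constants.
* **CTCF.** Integrated ROI intensity minus ROI area × mean background,
  with one background region per image reused for every cell. The
  background region is chosen automatically as a compact patch of the
  largest cell-free area (after dilating all cell masks by 8 px),
  grown to roughly the mean cell-ROI area so it is of similar size to the
  measured ROIs. CTCF is invariant under any uniform additive offset of
  the image.
* **Morphometrics.** Area is the pixel count; solidity is area over
  convex-hull area; the form factor is the circularity 4πA/P² with the
  Crofton perimeter estimator, which corrects the digital-boundary
  overcount so a rasterized disk scores ≈ 1 (it may marginally exceed 1,
  by < 1%, for near-circular digital shapes). Labels under 8 px are
  flagged and excluded from shape statistics because perimeter estimates
  are unstable there. Form factor and solidity are always reported
  alongside area, but the default panel scores nuclear morphology through
  **area only**; the panel file can be edited to score shape instead.
* **Cytoplasm without a stain.** A fixed-width ring (default 6 px) around
  each nucleus, with nearest-nucleus tie-breaking between neighbours.
* **N/C ratio.** Mean nuclear over mean cytoplasmic intensity per cell;
  an empty cytoplasm compartment yields a missing value, not an error.
* **Phagocytosis.** Fraction of cells with ≥ 1 detected spot, with the
  ≥ 2-spot fraction reported alongside, since both single- and
  multi-particle cells are informative.

## Tabular assays

* **ΔΔCt.** Technical replicates are averaged; ΔCt = Ct_target −
  Ct_reference per sample; the control baseline is the arithmetic mean of
  control-sample ΔCt values (computed per timepoint), and
  fold = 2^(−ΔΔCt). The mean-baseline choice (rather than per-pair
  normalization) is exposed through the grouping arguments.
* **Telomere T/S.** T and S quantities are interpolated from a linear
  regression of Ct on log2(concentration) of the standard dilution
  series — the standard practice for monochrome multiplex qPCR — each
  replicate gives a T/S ratio, and the reported TLR is the triplicate
  mean. QC fails when the intra-assay CV of the replicate ratios is
  ≥ 0.3 or replicates are missing. The TLR is in arbitrary units and
  invariant to a common scale factor on both signals. The score's
  telomere marker compares the treated arm against the control arm (not
  against an external donor standard).
* **Wound closure.** 100 × (area_first − area_last)/area_first from two
  binary gap masks; masks can also be derived by intensity thresholding
  of a phase-contrast-like image. Bounded above by 100, monotone
  decreasing in the final gap area; an empty first-day gap is an error.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: a control
and a treated arm, timepoints 3/7/14 days, ≥ 2 wells per arm (default 6)
and ≥ 20 cells per well (default 20), one scene per well per image-based
marker so the statistical unit matches the per-well analysis.

Measurement model, per scene (default canvas 300 × 300 px):

* Nuclei are perturbed ellipses (harmonics 3–6 of the boundary, default
  amplitude 0.04, axis ratio 0.8–1.0, radius 12 ± 1.2 px) placed by
  rejection sampling with a 4 px minimum gap and full clearance from the
  border; placement failure raises an error naming the nucleus density.
  When a target form factor is planted, the perturbation amplitude is
  bisected per nucleus until the rendered (Crofton) form factor matches
  within ±0.01, which keeps scene-level shape means within ±0.02.
* Channels are rendered as background (default 8) + per-cell levels +
  additive Gaussian noise (default σ = 1.5). There is no PSF, shot
  noise, vignetting or 3-D structure — by design, so that planted values
  are analytically recoverable.
* Foci/puncta are Gaussian spots (σ = 1.1 px, peak amplitude uniform in
  70–150, inside the 20–200 detection window) whose centers occupy
  randomly chosen sites of a per-cell hexagonal lattice (pitch 6 px,
  ≥ 3 px inside the compartment). The lattice guarantees that in-window
  cores are disjoint 4-connected components, making the planted count an
  exact oracle for the detector. A Poisson-drawn count exceeding the
  available sites is capped at the site count, and the cap is what the
  ground truth records; with the default geometry the cap binds rarely
  (large-rate tails only).
* Per-cell marker levels are log-normal around the condition × timepoint
  mean (per-cell log-SD 0.15); each well carries a log-normal multiplier
  whose log-SD is the effect spec's `dispersion` — this is the
  between-well biological variability that the per-well statistics see.
* Tables: qPCR Ct duplicates (technical SD 0.05 cycles, with a shared
  per-sample input-amount effect that cancels in ΔCt), ELISA duplicates
  (2% technical CV), telomere triplicates generated consistently with a
  10-point 2-fold standard dilution series, and wound-mask pairs whose
  planted closure percentage is recoverable to ±1 point (100 px gap).

The default effect preset plants the qualitative pattern of the
progerin-induction study — DNA-damage foci 0.8 → 6 per nucleus, H3K9Me3
60 → 28, SA-βGal 25 → 70, IL-6 15 → 60 pg/mL, IL-8 40 → 160 pg/mL,
Lamin B1 80 → 35, nucleus area 450 → 700 px at 14 days only, and null
effects for telomere, p16 and p21. The magnitudes are generator presets
chosen to be unambiguous at 6 wells per arm; the source study reports no
per-cell distributions or effect sizes, so these are not estimates of
real data. Identical parameters and seed reproduce bit-identical scenes
and tables.

What passing the end-to-end tests shows — and does not show: the pipeline
recovers planted effects of this simple measurement model through real
segmentation, spot detection and statistics; it does not demonstrate
robustness to uneven illumination, clumped or overlapping nuclei,
out-of-focus fields, or staining artifacts, which real microscopy data
exhibit and which would enter through the segmentation stage.

## Problem sizes and determinism

The shipped acceptance checks use the study conditions above (6 wells per
arm, 20 cells per well, 5 image markers → 180 scenes per study) and 20
independent study seeds for the end-to-end recovery check; calibration
uses 1000 per-well simulations per test path. All randomness flows from
`numpy.random.default_rng` seeds carried in the study design, so every
table a run writes is bit-identical under a repeated seed.

## Known limitations

* Segmentation is global-threshold based and assumes well-separated
  nuclei on a dark background (true for the generator; real data may
  need a dedicated segmenter behind the same interface).
* The two-way path assumes homoscedastic cells for its pooled residual
  variance; strongly variance-scaling effects are better served by the
  Welch path.
* The per-timepoint Sidak family is the number of timepoints only; with
  more than two conditions the treated-vs-control contrast must be named
  explicitly.
* Scores from different panels are not comparable; the panel definition
  travels with the scorecard for that reason.
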