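# Methods

This note documents the models, estimators and conventions implemented in
`copiiscreen`, the parameters that matter, what the synthetic generators do
and do not emulate, and the numerical edge cases.  Every number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## 1. Per-cell transport quantification

The reporter construct carries a fluorescent tag (total signal) and is
additionally detected at the cell surface with an antibody against an
extracellular epitope (surface signal).  Because the antibody can only bind
epitopes that reached the plasma membrane, the *whole-cell* sum of the
surface channel is the surface signal; no membrane-rim mask is needed, and
none is used.

Pipeline per 2D field:

1. **Background correction** — per channel, subtract the image's 5th
   percentile intensity and clip at zero.  This removes camera offset and
   uniform haze; adding a constant to a channel and re-correcting is a
   no-op.  The percentile is configurable; 5% assumes cells occupy well
   under 95% of the field.
2. **Nucleus segmentation** — Gaussian smoothing (σ = 2 px), Otsu
   threshold, small-object removal (< 40 px), distance-transform watershed
   to split touching nuclei (peak separation ≥ 7 px).
3. **Cell segmentation** — watershed on the inverted, smoothed cell-marker
   channel seeded with the nucleus labels, restricted to the Otsu
   foreground.  Cells partition the foreground and each contains exactly
   its seed.  An optional `merge_nucleus_distance` merges nuclei whose
   centroids are closer than the given distance into one seed before the
   watershed: multinucleated cells (the transfection-QC phenotype) carry
   adjacent nuclei inside one cytoplasm, and separate seeds would wrongly
   split them.  The option is off by default and turned on (30 px) when
   multinucleation is the readout.
4. **Per-cell ratio** — background-corrected channel sums over the cell
   region; ratio = surface / total; cells with non-positive total are
   flagged and excluded from spot means.  The ratio is invariant to common
   rescaling of both channels.

**Expression bins** (used by rescue and cargo-load analyses) are
left-closed, right-open: `< t1 → non`, `[t1, t2) → low`, `≥ t2 → high`;
thresholds default to the 33rd/66th percentiles of the expression channel
and are configurable.  **RUSH transport** is the mean release ratio minus
the mean non-release (leak-control) ratio, floored at zero; correction is
by subtraction of condition means because the assay design does not pair
release and non-release cells.

## 2. The transport score

For spot *i*: `score_i = (x_i − median(W_i)) / MAD(W_i)`, where `W_i` holds
the per-spot mean ratios of the 5×5 grid window centered on *i*.

Conventions, each of which the tests pin down:

- The **center spot is included** in the 25-value window.  The window is a
  local null model; with a robust median the center's own value moves the
  median only at the margin, and 25 values match the statistic's stated
  window size.
- **MAD carries no consistency constant** — the score divides by the raw
  median absolute deviation.
- **Edges truncate** the window (no mirroring — mirroring fabricates
  data); windows retaining fewer than `min_window = 12` values are flagged
  `insufficient_window` and not scored.  On a 16×24 chamber this excludes
  exactly the four 3×3 corner windows.
- **MAD = 0** (all window values equal) is flagged `degenerate_mad`; the
  score is NaN, never ±inf.
- Spots with fewer than `min_cells = 20` valid cells are flagged
  `low_cell_count` and drop out of both scoring and their neighbors'
  windows.
- Control spots stay in windows by default (the median tolerates sparse
  outliers; excluding them would thin edge windows); a flag removes them.
- Per-spot location is the **mean** ratio over cells (a median mode is
  available).

Two exact properties follow and are asserted: affine invariance
(`r → a·r + b`, `a > 0` changes no score by more than 1e-9) and strict
monotonicity in *x&#7522;* for a fixed window.  On a noise-free plate whose
only structure is a linear gradient, every full-window score is exactly 0;
truncated edge windows are asymmetric and retain gradient residue — one
reason corner windows are excluded.

### Null calibration — what self-normalization implies

The score is pivotal: if spot values are i.i.d. around the plate surface,
`(x_i − median)/MAD` has a fixed null distribution whose scale is
`≈ 1/0.674 ≈ 1.48` *independent of the noise magnitude* (the MAD of the
same noise sits in the denominator).  A fully null plate therefore shows
mean |score| ≈ 1.0 with ≈ 20% of spots beyond |1.5| — this is a property
of the statistic, not a defect of the implementation, and
`scripts/acceptance.py` reports it honestly
(`null_plate_mean_abs_score`).  Small null scores arise only when the
window spread is dominated by *structure the median removes* (a smooth
gradient steep enough to dwarf the per-spot noise) or by real biological
spot-to-spot variation.  In a production screen the latter is what the MAD
estimates, which is exactly why thresholds like −1.5 are anchored on
positive controls rather than on a theoretical null.

## 3. Plate quality control

A plate passes when:

- the **median positive-control score** ≤ −1.5 (coatomer knockdowns must
  show strong inhibition);
- the **median signed negative-control score** lies within ±0.5 of zero.
  This is a drift/bias check.  Individual windowed scores of null spots
  are unit-scale by construction (§2), so a per-spot bound would reject
  every honest plate; the published anchor values for nontargeting
  controls (0.08 and −0.16) are aggregate medians, consistent with the
  drift reading.  The stricter every-spot rule is available as
  `negative_rule="max"`.
- when a multinucleation readout is supplied: the fraction of
  multinucleated cells on the transfection-QC spots ≥ 0.5.

All three numeric cutoffs are conventions exposed in `QCThresholds`; a
missing control class fails the plate with an explicit reason.  Failed
plates are excluded from aggregation and logged.

## 4. Replicates and hit calling

Per (siRNA, background) condition the median score over biological
replicates is used, defined only for ≥ 3 replicates; under-replicated
conditions are retained in the output with `included = False` and a
reason.  The chamber-wide background siRNA is invisible to within-plate
scores (it shifts every spot equally), so its single-knockdown score is
read from the nontargeting spots on that background's plates — near zero
by design, matching screening conditions titrated so the background alone
does not move transport.

A double knockdown is a hit iff `classify_effect(double) ≠ none`
(|score| ≥ 1.5, thresholds symmetric and configurable) **and**
`|double − (single_gene + single_background)| > 1`.  The absolute
difference captures both aggravating and alleviating interactions; a
signed mode restricts to deviations in the effect's direction.  Ranking is
by |double| descending, ties by |difference| descending, then gene id —
the tie rules are conventions.

### False-positive behavior of the additivity rule

Because null scores are unit-scale (§2), the two gates sit at ≈ 2.3 σ of
the null median-of-5, so a screen of ~1,700 null conditions admits on the
order of tens of false pairs; and when many library genes carry persistent
single effects beyond 1.5 window-MADs, window-MAD estimation jitter
(cv ≈ 0.2 for 25 values) feeds `|score| × jitter` into the difference and
produces further false calls.  Planted strong interactions are unaffected
— they rank far above the false tail (the acceptance script reports the
top-ranked fraction).  Practical consequence: treat the hit table as a
*ranking* to be truncated by effect size and validated, not as an
FDR-controlled discovery list.

## 5. 3D puncta quantification

Per channel: 3×3×3 median filter (noise), subtraction of a 9×9×9 median
background, clip at zero.  The small median trims a diffraction-limited
Gaussian peak to roughly half its amplitude (the rank-14 order statistic
of 27 samples); the detection threshold accounts for this by being set in
*filtered-noise* units: `auto_seed_threshold` estimates the filtered
residual's robust σ and places the threshold at 7 σ.  Seeds are strict
3×3×3 local maxima above threshold (plateaus contribute one seed);
watershed segmentation from the seeds within the half-threshold mask
splits touching structures.  Adjacent labels are re-merged when the
intensity saddle on their interface exceeds 0.7 × the dimmer peak: a real
pair of touching puncta keeps a deep valley between its maxima, a
shot-noise-split peak does not.  Bright connected regions larger than
`min_cluster_volume = 200` voxels (an order of magnitude above a punctum)
are treated as Golgi-like clusters: returned separately and excluded from
spot analysis before counting.  Spots are assigned to cells by centroid
containment; per-cell output is structure count, integrated spot
intensity and integrated cell intensity, and condition summaries refuse
to aggregate fewer than 100 cells.  When a stack declares its z spacing,
z filter radii scale by pixel/z-spacing; otherwise elements are isotropic.

Measured on the synthetic stacks (28×64×64, background 20 counts, Poisson
plus Gaussian read noise σ = 2): counts are exact at SNR ≥ 5, with or
without a cluster, and the absolute count error is monotone non-increasing
over SNR ∈ {2, 5, 10, 20} (at SNR 2 the puncta sit below threshold and are
largely missed — by design the threshold favors precision).

## 6. Focal adhesions

The in-focus slice maximizes the **normalized variance** `σ²/μ` (standard
autofocus metric; ties break to the lowest index, an all-zero stack is
flagged and yields 0).  Adhesions are segmented by Otsu thresholding the
maximum projection of the three slices centered on that plane (clamped at
stack edges), with a 5-px minimum size; Otsu makes the labels invariant to
positive intensity rescaling.  Reported per field: count, total area,
mean size, total intensity, and per-cell values divided by the segmented
nucleus count (NaN when no nuclei; cell-boundary normalization is not
implemented — nucleus count is the default and only mode).  Condition
summaries refuse fewer than 50 cells.  On the synthetic stacks the
planted focus plane is found in 100% of 200 SNR-5 stacks and total area
lands within 2% of truth (10% asserted).

## 7. qPCR fold change

`ddct_fold_change` implements relative quantification against a
housekeeping gene: `fold = 2^−ΔΔCt` with
`ΔΔCt = (Ct_target − Ct_hk)_treated − (Ct_target − Ct_hk)_control`.
Non-finite Ct values are rejected.

## 8. Synthetic generators — what they emulate

**Screen plates.**  Per-cell ratio = base + gene effect + background
effect + interaction + gradient(row, col) + N(0, σ), truncated at zero;
cells per spot ~ Poisson(200); base 0.5, σ = 0.15 (30% CV, so the SE of a
spot mean is ≈ 0.011).  The plate gradient is a fixed tilted plane with
mild curvature, zero-mean, peak-to-peak 20% of base — enough to exercise
the windowed normalization.  The spotting design places 848 library
siRNAs over 378 genes (2–3 independent siRNAs per gene, round-robin) on
four 16×24 chambers, the remaining spots cycling through two nontargeting
controls, two coatomer positive controls (effect −0.3) and a
transfection-QC siRNA whose spots binucleate 60% of their cells (baseline
5%).  The same spotting serves every background and replicate, as with a
physical chamber lot.

The default truth emulates a **titrated screen**: unplanted library genes
are inert, planted genes carry weak single effects (uniform within
±0.05 ratio units) and their designated (gene, background) pair an
interaction of −0.25 present only in the double knockdown.  This is the
regime in which planted interactions are the only strong structure and
the worked examples (top-ranked recovery) hold.  `library_effect_sd > 0`
adds library-wide main-effect spread; see §4 for why a library full of
strong single effectors degrades the specificity of the difference rule.
What the plate generator does **not** emulate: spatially correlated cell
clumping, per-replicate gradient changes, siRNA-specific off-target
signatures, edge evaporation beyond the smooth gradient.  Passing tests
therefore certify the statistics and bookkeeping, not robustness to every
real-plate pathology.

**2D fields.**  Non-overlapping disk cells with per-cell expression
levels, surface = programmed ratio × total pointwise, Gaussian blur
(σ = 1 px), camera offset 20 and read noise σ = 3 on every channel;
nuclei as disks, binucleated cells as two adjacent nuclei in one
territory.  Programmed ratios are recovered within ±0.02 by the full
segmentation pipeline (±0.05 asserted).  Not emulated: membrane rims,
cell-shape diversity, focus drift.

**3D stacks.**  Isotropic Gaussian puncta (σ ≈ 1.2–1.3 voxels, pairwise
separation ≥ 7, kept ≥ 18 voxels away from the optional cluster so that
every planted punctum has a recoverable identity), an optional bright
ellipsoidal Golgi-like cluster (1.5× punctum amplitude, σ = (2.5, 6, 6)),
background 20 counts, Poisson + Gaussian read noise; SNR is peak amplitude
over background noise σ.  Not emulated: anisotropic PSF, z attenuation,
vesicle motion blur.

**Adhesion stacks.**  Elongated ellipses (semi-axes 8–14 × 3–5 px) sharp
in one designated slice; other slices hold Gaussian-blurred copies
attenuated as exp(−Δz²/2·0.8²), emulating confocal optical sectioning —
this attenuation is what makes the normalized-variance autofocus sharp.
`size_scale` scales ellipse areas for "enlarged adhesion" conditions (the
pipeline recovers a 2× mean-size condition within 10%).  A nucleus channel
carries disk nuclei.  Not emulated: cytoplasmic vinculin pools, adhesion
turnover, uneven illumination.

Every generator is deterministic given its seed, and every dataset is
emitted with its serialized ground truth (JSON round-trip is tested).

## 9. Problem sizes

The test suite and acceptance script run: full-scale screens (3 backgrounds
× 5 replicates × 4 chambers × 384 spots ≈ 4.6 M simulated cells per
screen; 10 screens in the recovery test, 3 in the script), 28×64×64 spot
stacks (a few per SNR level), 9×128–192² adhesion stacks (200 for the
autofocus accuracy estimate), and 256–384² 2D fields.  These sizes keep
each stage's sampling error an order of magnitude below the asserted
tolerances while the whole suite completes in minutes on one CPU.
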