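# Methods

`nucleoshuttle` quantifies stress-induced shuttling of nuclear proteins
between nucleoli and nucleoplasm from multi-channel immunofluorescence
images. This note records the models, defaults and numerical choices the
package is built on, and what its synthetic validation does and does not
demonstrate.

## The measurement model

Each field carries three co-registered channels: a DNA dye defining the
nuclear area, a nucleolar marker (e.g. fibrillarin) defining the nucleolar
area, and the protein of interest. For every nucleus the protein channel is
partitioned into the nucleolar compartment (union of that nucleus's
nucleoli) and the nucleoplasm (nucleus minus its nucleoli — peri-nucleolar
pixels are nucleoplasm). The per-cell statistic is

    R = mean(protein | nucleoli) / mean(protein | nucleoplasm)

reported alongside the display convention `R − 1`, so 0 marks a homogeneous
distribution, positive values nucleolar accumulation, negative values
nucleolar depletion. Means (not medians) are used, and no background
subtraction is applied by default; an optional constant-subtraction
argument exists but is off. The ratio is scale-invariant, and adding a
constant offset to the protein channel moves every ratio toward 1 — which
is why uncorrected camera offsets compress, but never invert, the effect.

Integrated intensities over the same partition are reported in every
record. `sum_total` is computed as `sum_nucleolar + sum_nucleoplasmic` over
the disjoint partition, so the conservation identity holds to machine
precision by construction; its scientific content is that pure
compartment shuttling leaves the per-nucleus total unchanged while
degradation or synthesis does not. Whether a downstream analysis should
compare per-cell means or integrated sums is genuinely ambiguous for this
assay, so both columns are always emitted and neither is privileged.

Cells without a segmented nucleolus (or below `min_nucleolar_area_px`,
default 1 px) carry an undefined ratio and `qc_flag=no_nucleolus`; a zero
nucleoplasmic mean gives `qc_flag=degenerate_denominator`. Undefined cells
never enter ratio statistics and are counted separately.

Per-cell ratios (matching analyses that report ">90 cells" per condition)
are the default; a pooled-pixels field-level ratio is available as
`pooled_field_ratio` for workflows that measure whole images.

## Categories

The manual three-way scoring of cells — nucleolar signal stronger than
nucleoplasm ("strong"), homogeneous ("medium"), weaker ("without") — is
operationalized as a symmetric band around R = 1: strong if R > 1 + δ,
without if R < 1 − δ, medium otherwise. The human judgment of
"homogeneous" has no published width, so δ = 0.1 is a declared,
configurable default, not a measured constant. Category fractions are
computed over defined-category cells only and sum to 1 per condition.

## Segmentation

All operators are classical and deterministic (no trained components):

- **Nuclei** (dye channel): Gaussian smooth (σ = 2 px) → global Otsu (or
  fixed) threshold → fill holes → optional watershed split of touching
  objects, seeded by local maxima of the Euclidean distance transform
  (min seed distance 15 px; the EDT is smoothed with σ = 1 px for seeding
  only, to avoid spurious ridge maxima on elongated nuclei) → drop objects
  < 500 px → drop border-touching objects (default on, because truncated
  nuclei bias areas) → relabel contiguously in scan order.
- **Nucleoli** (marker channel): thresholded within nuclear pixels only,
  per-nucleus Otsu by default so each cell's staining level sets its own
  cutoff (a global within-nuclei scope is switchable); components < 20 px
  dropped; each nucleolus is clipped to and assigned its parent nucleus, so
  the containment invariant (nucleolus mask ⊆ parent nucleus) holds by
  construction. A nucleus whose within-nucleus marker is constant yields
  zero nucleoli and is flagged downstream rather than erroring.

Hole filling runs before area filtering deliberately: nucleoli are
chromatin-poor and appear as holes in the dye channel, and the nuclear area
must include them for "nucleus minus nucleoli" to be the correct
nucleoplasm.

Exact-recovery analyses on noiseless synthetic fields use
`smoothing_sigma_px = 0`: without noise there is nothing to smooth, and
pre-smoothing would shift threshold contours by a boundary pixel, which is
expected behaviour, not an error. At the default noise level the default
σ = 2 is used and fidelity is scored by object-level IoU instead.

Segmentation quality is scored by `mask_iou`: truth objects are matched to
predicted objects by maximal pixel overlap; each truth object scores
intersection-over-union against its match, unmatched objects on either side
are reported, and `mean_iou` averages over truth objects counting unmatched
truth as 0.

## Statistics

The independent experiment is the unit of replication. `aggregate` first
averages cells within (condition, replicate), then computes mean and SEM
(sd/√n, ddof = 1) across replicate means, so replicates with unequal cell
counts weigh equally. A single-replicate condition reports an empty SEM
with a warning.

- **Chi-square**: Pearson test on the conditions × categories count table
  (counts pooled across replicates; raw counts, never percentages), no
  continuity correction — so the 2×2 statistic equals the closed form
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)). All-zero margins are a named error.
- **Two-way ANOVA**: fixed-effects with interaction, fit on replicate-level
  means (statsmodels OLS + anova_lm, type-II sums of squares, which
  coincide with the textbook decomposition on the balanced designs this
  package produces). With < 2 observations in any cell the interaction is
  dropped with a warning. Zero-variance inputs report F = 0, p = 1 by
  convention (threshold: term SS ≤ 1e−12 × total SS) so degenerate
  synthetic inputs don't crash or NaN a pipeline. No multiple-testing
  correction is applied.
- **Stars**: '***' iff p ≤ 0.001, '**' iff p ≤ 0.01, '*' iff p ≤ 0.05.
- **Kinetics**: a time course is summarized by sign crossings of the
  grand-mean displayed ratio at 0 (i.e. R crossing 1, the interpretive
  boundary between accumulation and depletion): release is the first
  timepoint with a negative grand mean, recovery the first later timepoint
  back at ≥ 0; absent crossings are reported as flags, never errors.

## Synthetic fields

Because validation needs ground truth no real image can provide, the
generator renders the assay with known geometry, enrichment and noise:

- Geometry: non-overlapping, axis-unaligned elliptical nuclei fully
  interior to the image (rejection sampling, bounding-circle separation
  test, cap 10 000 attempts — exceeding it raises an error naming the
  crowding parameters); each nucleus holds a sampled number of circular
  nucleoli, placed strictly inside with a ≥ 1 px gap between siblings so
  distinct nucleoli remain separable connected components. Containment is
  enforced at pixel level, so ground-truth masks satisfy the same
  invariants the segmentation guarantees.
- Intensities (noiseless): background everywhere; dye at
  `nuclear_dye_intensity` in nuclei, attenuated by `nucleolar_dye_dimming`
  (default 0.4) inside nucleoli because nucleoli are chromatin-poor —
  keeping the dye channel honest while staying above background; marker at
  `marker_intensity` inside nucleoli only; protein at
  `nucleoplasm_mean_intensity` in nucleoplasm and `e ×
  nucleoplasm_mean_intensity` in nucleoli. With noise off, the realized
  per-nucleus enrichment equals `e` to machine precision, which anchors the
  whole quantification chain.
- Noise: per pixel, `Poisson(I·photon_scale)/photon_scale +
  N(0, read_noise_sigma)`, clipped at 0 — the standard shot + read model.
- Defaults: 1152 × 1152 px fields (the assay's acquisition size); 12
  nuclei per field, so ~8 fields reach the > 90 cells a condition
  comprises; nucleus radii 40–70 px and 2–5 nucleoli of 5–15 px radius
  (plausible for adherent human carcinoma cells at ~63× — typical counts
  and size distributions are not published for this assay, so these are
  declared defaults, not measured values); intensities
  background 5 / nucleoplasm 100 / dye 200 / marker 150 AU;
  `photon_scale = 1` (≈10% shot noise at nucleoplasm level) and
  `read_noise_sigma = 2`.
- Determinism: one `numpy` Generator seeded from the spec drives geometry
  and noise; identical spec + seed is bit-identical.

### Kinetics model

The true enrichment follows a piecewise-exponential release-then-recovery
trajectory:

    e(t) = e_floor + (e0 − e_floor)·exp(−k_rel·t)              for t ≤ τ
    e(t) = e(τ) + (e0 − e(τ))·(1 − exp(−k_rec·(t − τ)))        for t > τ

continuous at the recovery onset τ, monotone down then up, with
e(t) → e0 as t → ∞ when k_rec > 0 (full relocalization). The release
floor `e_floor` is part of the model because genotoxic release drives the
measured ratio *below* 1 (nucleoli largely emptied of the protein), which
is exactly the regime the crossing-based kinetics summary detects; with
`e_floor = 1` the form reduces to the classical `1 + (e0−1)·f(t)`
homogeneous-endpoint model. Defaults (e0 = 3, k_rel = 2 h⁻¹, τ = 3 h,
k_rec = 0.5 h⁻¹, e_floor = 0.5) reproduce the reported phenomenology of
oxidative-stress-induced shuttling: full release within ~2 h, relocation
beginning ~4 h, complete by ~8 h. Time-course fields are re-sampled per
timepoint from `seed + index` — fixed-cell imaging, not live tracking.

### What passing synthetic tests does not show

The generator omits point-spread-function blur, spectral bleed-through,
intra-compartment texture, mitotic and apoptotic cells, uneven
illumination and cell-to-cell staining variability beyond what per-nucleus
thresholding absorbs. Exact mask recovery and tight enrichment recovery on
these fields therefore validate the *computational* chain — segmentation
logic, partition arithmetic, statistics — not performance on real
microscopy, where segmentation parameters would need tuning and accuracy
would be lower.

## Scavenging assay

Activity is `(A_sample − A_background)/(A_negative_control −
A_background)` from 510 nm readings of the Fe²⁺–phenanthroline assay; ~1
means full protection of the Fe(II) signal, ~0 none. A non-positive
denominator is an error; negative numerators (optically impossible,
i.e. noise) clip to 0 with a logged warning. Concentration series are
metadata only; no EC50/4PL fit is performed.

## Problem sizes used in validation

The shipped checks run on full-size default fields: 20 fields for
conservation, 5 fields (60 nuclei) per enrichment level for recovery at
e ∈ {0.5, 1, 2, 4}, 20 seeds for noisy segmentation fidelity, 3 replicates
× 5 timepoints for the end-to-end kinetics run, 1000/100 simulations for
ANOVA null calibration and power. These sizes make the stochastic checks
stable (binomial SE on the null rate ≈ 0.7 points at n = 1000) while a
full run stays in the low minutes on one CPU.

## Known limitations

- 2D only; no z-stacks, no live-cell tracking.
- The nucleolus is one compartment; fibrillar-centre/dense-fibrillar/
  granular substructure is out of scope.
- Mitotic cells are not filtered; border exclusion is the only cell-level
  QC beyond the area filters.
- ANOVA assumes fixed effects on replicate means; no mixed models or
  post-hoc tests.
- The categorized and ratio-based analyses share masks but are not forced
  to agree; δ controls their correspondence.
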