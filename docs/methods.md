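# Methods

This note documents the models, estimators and numerical choices behind
`speckpull`, and what its synthetic benchmarks do and do not establish
about real data.

## Acquisition model and coordinate conventions

Coordinates are in nanometres with the origin at the top-left of the field
of view, x right and y down (the convention of common localization-table
formats); pixel indices are 0-based with half-open intervals. Defaults
encode the assay's acquisition constants: camera pixel 103.5 nm at the
sample, 512×512 px FOV, 8000 frames per dSTORM acquisition at 30 ms
exposure, and 50-frame diffraction-limited movies. Reconstructed
(super-resolution) images use a 15 nm render pixel — about half the ~30 nm
optical resolution limit, so the resolution cut at 30 nm spans two render
pixels. These provenance-bearing defaults are listed in
`speckpull.config.PARAMETER_PROVENANCE` and emitted in every pipeline
report.

## Synthetic data

The generator emulates the statistical structure the analysis consumes,
not the photophysics underneath it.

* **Blinking model.** Each fluorophore emits a Poisson number of blink
  events with mean set from the target localizations per aggregate
  (default 58, the assay's measured average); events are spread uniformly
  over frames. There is no dark-state machine and no photobleaching decay:
  counts and morphology, which is all downstream stages consume, only
  depend on the marginal event statistics. A consequence used by the
  tests: localizations per aggregate are Poisson (variance/mean ≈ 1), and
  per-frame-block localization counts are flat.
* **Labelling.** Fluorophores are placed uniformly over an ellipse
  interior; intra-speck labelling density is not known for real specks, so
  it is a parameter, not an assertion.
* **Localization noise.** Isotropic Gaussian with per-localization σ drawn
  from a truncated normal, mean 17 nm, sd 7 nm, minimum 1 nm — the assay's
  measured lateral uncertainty.
* **Diffraction-limited movies.** Each frame is Poisson background plus
  Gaussian-PSF spots (σ ≈ 1.3 camera px) with Poisson photon noise,
  clipped to uint16. No EM-gain or read-noise model.
* **Cohorts.** Per-subject marker counts are negative binomial —
  overdispersion is the realistic regime for per-FOV aggregate counts —
  with disease means equal to control means times per-marker fold changes
  (defaults bracket the 1.5–4.2× rise observed for specks in disease
  serum; the Abeta default is 1.0, which is what makes it usable as a
  ratio denominator). Per-subject morphology sets are drawn from a
  two-component mixture: "small round" (equivalent diameter 35–150 nm,
  circularity 0.7–1.0) and "large irregular" (150–1000 nm, 0.2–0.7); the
  disease effect shifts the small-round mixture weight (default base 0.30).
* **Denaturation.** Counts follow N₀·exp(−c/cₑ) with multiplicative
  lognormal noise of a given CV, averaged over 12 simulated FOVs.

What passing on this generator does **not** show: robustness to structured
background (cellular debris, surface non-uniformity), emitter re-blinking
correlations, chromatic/field-dependent aberrations, or label-density
variation across real speck conformations. Those require real calibration
samples.

## Spot counting

The 50-frame movie is frame-averaged (SNR gain ≈ √50); background is a
41×41 median filter (2×20 px radius + 1), and the detection threshold is
k·σ over the residual with σ the median absolute deviation × 1.4826 —
robust to the bright spots themselves contaminating the noise estimate.
Pixels above threshold are grouped into 8-connected ("path-connected")
components, and components outside a 2–200 px area band are discarded.
Counting is therefore invariant to positive intensity rescaling and
monotone under added spots. Spots touching the image border are kept:
counts, not shapes, are the endpoint at this stage. Control wells (buffer,
no-capture, non-target detection IgG) gate validity — a sample passes when
it exceeds every control by a configurable factor (default 3×) — and are
never subtracted from the signal.

A saturated (constant non-zero) image raises an "uninformative image"
error rather than returning a count of zero or one.

## Morphometrics

Rendering is a 2-D localization-count histogram (integer image; pixel sum
equals the table length). Segmentation binarizes at ≥ 1 localization,
labels 8-connected components, and discards components carrying fewer than
`min_localizations` (default 5) total localizations — the simplest rule
consistent with counting localizations per aggregate. Area is the binary
mask area (pixel count × pixel area); the alternative,
localization-weighted area, is deliberately not used, and this choice is
flagged here rather than asserted as the only reasonable one. Perimeter
uses the Crofton approximation (pixel-edge counting systematically
overestimates P and deflates circularity); circularity C = 4πA/P² is
clipped to 1 because discrete perimeters can undershoot. Degenerate
single-pixel masks, whose Crofton perimeter can vanish, fall back to the
4-edge pixel perimeter. Reported values are stored at full precision;
display rounding/truncation is applied only when formatting.

**Mask-based area needs adequate sampling density.** A ≥ 1-localization
mask tracks the true support only when the expected localization count per
interior render pixel is ≳ 2 (interior holes decay as e^(−density), while
the boundary blur from 17 nm noise roughly offsets the remaining deficit
near the 50 %-density crossing). The disk-recovery benchmark therefore
scales expected localizations with true area at 2 per render pixel — which
is also what the assay's measured average implies: 58 localizations on a
typical ~100 nm speck ≈ 35 render pixels ≈ 1.7 per pixel. With that
density the render→segment→d_area chain recovers disk diameters of 50–500
nm within max(2 render px, 10 %).

Drift correction renders consecutive frame blocks (default 1000 frames),
registers each to the first block by sub-pixel phase cross-correlation,
and interpolates the per-block shift linearly in frame; it replaces a
published mean-shift tracker with the standard redundant cross-correlation
approach because the contract downstream needs — sub-pixel registration of
block images — is the same. Blocks with fewer than 100 localizations make
registration unreliable; the correction then degrades to identity with a
warning.

Frame-sufficiency diagnostics re-segment the table truncated at a series
of frame breakpoints (2k/5k/8k/11k/14k/16k by default, clipped to the
acquisition) and report the IQR of area and circularity per breakpoint
plus localization counts per inter-breakpoint block; stable IQRs from 8k
frames and flat block counts reproduce the saturation behaviour expected
of a well-sampled acquisition.

## Distribution statistics

ECDFs are right-continuous; difference curves are evaluated on the pooled
sorted grid with the asymptotic two-sample Kolmogorov–Smirnov band
c(α)·√((n+m)/nm), where c is the Kolmogorov-distribution quantile
(c(0.01) = 1.628). The two-sample KS test uses the asymptotic p-value.

The threshold scan computes, for every pair on an area × circularity grid
(default: area log-spaced over the pooled 5th–95th percentile in 40 steps;
circularity 0.05-spaced in [0, 1]), the per-subject fraction of aggregates
with A ≤ a and C ≥ c — subjects, not pooled aggregates, are the unit of
the group comparison, matching per-participant box plots — and the
difference in group means, with a permutation test sharing one seeded set
of label permutations across all cells (the scan is vectorised over the
grid). Per-cell p-values are **not** multiple-testing corrected: the
procedure is explicitly a maximizing scan, and the result object carries a
`multiple_testing_corrected=False` flag.

Two design choices required care beyond the obvious scan:

* **Plateau-edge selection.** The joint fraction is piecewise constant in
  (a, c), so |Δf| is maximal on a plateau whose lower-area edge is the
  actual boundary between morphology populations; a raw argmax lands
  anywhere on the plateau by noise. Among cells whose |Δf| is within one
  permutation-SE of the maximum — the SE of the *paired* cell-minus-argmax
  difference, which is much tighter than the marginal SE because all cells
  share subjects — selection prefers the smallest area cutoff, then the
  largest circularity cutoff, then the largest |Δf|, then the smaller p.
  With exact ties this reduces to plain smaller-area tie-breaking.
* **Global significance.** The boolean `significant` uses the permutation
  distribution of the grid-wide max |Δf| (computed for free from the
  shared permutations), not the per-cell p at the selected cell, because a
  selected-cell p is biased by selection and would flag "significant"
  under the null far more often than α. The per-cell p grid and the exact
  (enumerating) permutation p at the winning cell are both still reported.

## Cohort statistics

AUC is rank-based (Mann–Whitney with mid-ranks, ties count ½) — exact
under ties, unlike a trapezoid on a coarse ROC curve; scores are oriented
with disease positive and AUCs below 0.5 are reported as-is (a
one-directional biomarker claim is not silently flipped). The permutation
test on the difference of group means enumerates all C(n+m, n) label
assignments up to 184 756 (10 vs 10) and otherwise uses a seeded
Monte-Carlo with 10⁵ resamples and the observed statistic counted in the
reference set; statistic comparisons carry a relative 1e−12 tolerance so
float round-off cannot drop tied assignments. Group sizes are compared by
the exact two-sided binomial test at p₀ = 0.5.

Composite biomarkers form the closure of the printed forms: singles, sums
of two, ordered ratios, and ratios of a two-marker sum to a third marker —
k + C(k,2) + k(k−1) + C(k,2)(k−2) expressions for k markers, ranked by
AUC with a lexicographic tie-break for determinism. Morphology-derived
metrics (e.g. the morphologically distinct fraction) enter the grammar as
ordinary markers when supplied. The group-maximum normalization of the
denominator marker divides each subject's value by the maximum within
their *own diagnostic group*; this reproduces the described procedure
faithfully, but it leaks the diagnostic label into the score, so every
call emits a prominent warning — the intent is reproduced, not
second-guessed. Fold changes are ratios of group means (medians also
reported; means are primary because the choice is otherwise
underdetermined).

Power for the two-sided two-sample t-test comes from the noncentral t
distribution with noncentrality d·√(n/2) and 2n−2 degrees of freedom; at
d = 2, n = 10/group, α = 0.05 it gives 0.988 ("99%"), and the tests
cross-check it against an independent 10⁵-replicate Monte-Carlo and
against statsmodels. Precision CVs are 100·SD/mean per sample; intra-assay
averages within-plate replicate CVs, inter-assay averages CVs of per-plate
means, both flagged against the 20 % acceptability bound.

## Stability

The denaturation fit is log-linear least squares of log N on c (slope
−1/cₑ): robust at small counts, exact for noiseless exponentials, and
scale-equivariant. Zero counts are replaced by 0.5 (continuity correction)
and flagged; a non-decreasing series is flagged `decaying=False` with
cₑ = ∞ instead of producing a spurious negative scale. By construction the
fitted curve at c = cₑ equals N₀/e ≈ 0.4·N₀. Immunodepletion is
1 − after/before, clipped to [0, 1]. The two-stage experimental protocol
(coarse 0.8–4 M, fine 0.05–0.72 M) is represented as one concatenated
curve; no thermodynamic unfolding model is fitted.

## Pipeline, determinism and problem sizes

`run_pipeline` chains count → morph → stats → biomarker from one config;
all randomness derives from a single master seed, reports carry the seed,
a parameter hash (excluding the output directory) and the package version,
and identical config + seed yields byte-identical bundles (JSON keys
sorted, non-finite ratios serialized as null). A stage failure aborts with
the stage named; completed stages' outputs are retained.

Test and benchmark problem sizes are chosen to exercise the estimators at
meaningful scale while keeping the suite quick: 128–512 px FOVs, 2000–16000
frames, cohorts of 4–20 subjects per group with 60–300 aggregates each,
100-seed batteries for calibration properties, and 10⁵ resamples for
Monte-Carlo cross-checks. The full-scale default pipeline (512 px, 8000
frames, 20 + 20 subjects) runs in well under a minute.

## Known limitations

* Segmentation is plain connected components on the rendered mask;
  touching aggregates merge (no watershed/DBSCAN), and mask area is
  density-dependent at low localization counts (see above).
* The KS band and test use asymptotic critical values; at very small n the
  band is approximate.
* The composite grammar is the closure of the printed forms only; it does
  not explore weights, differences, or more than three markers per
  expression.
* Group-max normalization leaks labels by construction (warned at every
  call); in-sample AUCs on normalized ratios are optimistic, and no
  cross-validation machinery is provided.
* The simplified blinking model cannot answer photophysics questions
  (duty cycle, bleaching kinetics); it is adequate only for count and
  morphology statistics.
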