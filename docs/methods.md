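# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind each module. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Imaging pipeline

**Preprocessing.** Each single-channel raster is (optionally) resized by a
single isotropic factor — bilinear for intensities, nearest-neighbor for
masks — then min–max normalized per image, gamma-corrected
(`out = 255 · norm^γ`, default γ = 0.8, a mild perceptual-contrast boost),
and clipped/rounded to 8-bit. The mapping is monotone, so segmentation
order is preserved; a constant image (including all-zero) maps to all
zeros rather than dividing by a zero range. Resizing precedes
normalization so intensity statistics reflect the working resolution.

**Segmentation.** Masks are cut on the preprocessed raster at fixed global
per-channel thresholds. "Suprathreshold" is read as strictly
greater-than: this makes threshold 255 yield an empty mask and threshold 0
on a {0, 255} rendering reproduce the mask exactly; the inclusive
alternative is one flag (`strict=False`). Thresholds are deliberately
required configuration with no default — they are the free parameter that
determines every downstream number, and a silent default would fabricate
it. All parameters are frozen per batch (`SegmentationParams` is
immutable) so fields within a batch are comparable.

**Metrics.** Percent area is suprathreshold pixels over field pixels. The
"merged" denominator is a provided composite mask when present (passed
through verbatim; RGB composites are never decomposed implicitly — the
pipeline consumes single-channel files only), otherwise the pixelwise
union of the channel masks. Pairwise overlap is the AND-area divided by
the merged area (spatial prevalence in the scene) or by the target's own
area (fraction of target signal coincident with the comparison marker).
Zero denominators flag the metric as missing (NaN), never zero; a zero
dead-cell area likewise flags the live:dead ratio undefined rather than
raising. Aggregation over a well's fields uses the arithmetic mean and
sample SD per metric, excluding missing values pairwise with the
effective n recorded.

## Synthetic fields

Cells are discs of configurable radius placed on a jittered grid whose
pitch guarantees that discs never overlap or leave the frame; doubling
the cell count therefore doubles the true area fraction (up to grid
capacity). The radial intensity profile is Gaussian with scale 2×radius,
cut hard at the mask boundary — intensity falls to ~88% of peak at the
edge, so the object boundary is a sharp step, as for a well-stained
soma. Consequences: at zero blur and zero noise the suprathreshold region
at any positive cut below the edge intensity equals the true mask
exactly, and under additive Gaussian noise up to ~10% of the 8-bit range
a mid-range threshold sits several noise SDs away from both background
and foreground, keeping recovered areas and overlaps within fractions of
a percentage point. Colocalization between an ordered channel pair (a, b)
is produced by co-placing `round(f · n_cells)` shared centers, so the
realized |A∩B|/|A| equals the request up to rounding; a channel whose
shared allocations exceed its cell budget raises an explicit
infeasibility error. `true_overlap_fraction(a, b)` is stored
target-referenced (|A∩B|/|A|, matching the pipeline's
`overlap_pct_target`); absolute AND areas never exceed either channel's
area. All ground-truth comparisons carry a one-pixel tolerance, since
rasterization rounds areas to whole pixels.

Randomness is threaded from one master seed through
`numpy.random.SeedSequence` substreams (placement, then one per channel
or gene), making outputs bit-identical per seed. Defaults (50-cell
density at 256×256, radius 6 px, peak 200, zero blur/noise) are a
generator choice — the magnification-to-pixel scale of real 40× fields
is not modeled — and are freely configurable. Not emulated: point-spread
functions, 3-D stacks, photobleaching, illumination gradients,
per-cell intensity variation. Passing recovery tests therefore shows the
pipeline arithmetic is correct under the stated noise model, not that any
particular threshold choice is right for real micrographs.

## qPCR quantification

ΔCt pairs each target replicate with the reference-gene replicate of the
same (status, dose, replicate); rows with no reference partner are
dropped with a warning, never imputed. Amplification efficiency is fixed
at 2 (the classic ΔΔCt assumption) with a config hook. The group-level
fold change defaults to the arithmetic mean of per-replicate fold changes
(matching per-point replicate displays around bar means); the geometric
form 2^(−mean ΔΔCt) is one flag away. Under both calibrator conventions
the fold change evaluated at the calibrator group's own mean ΔCt is
exactly 1, and adding a constant to every Ct of one gene leaves its fold
changes unchanged (the constant cancels in ΔΔCt).

**Reference-gene stability.** The selector operates directly on Ct values
(Ct is log2 expression up to affine terms) with a two-way decomposition
per experimental group: Ct = gene-group level + per-sample
(template/loading) effect + noise. Design choices, made where the
published variance-decomposition family leaves room:

* Sample effects are estimated within each group from gene-centered
  residuals, where group-level expression differences cancel exactly —
  so one candidate's group bias cannot leak into the others' bias
  estimates through the centering.
* The candidate-average subtraction mixes a 1/k share of every other
  gene's noise into each residual; the intragroup variances are
  deconvolved from this mixing (solving the k-gene linear system; for
  k = 2 the total is split evenly, as the system is singular), and
  clipped at zero.
* Each gene's intergroup bias d is the deviation of its group means
  around its own grand mean, on its own Ct scale. A per-gene
  between-group variance component γ²_j is estimated by method of
  moments and shrinks d empirically-Bayes style; per-gene (rather than
  common) components keep one wildly noisy candidate's small-df variance
  estimates from collapsing the shrinkage for all genes.
* Stability ρ_j = mean over groups of (|shrunk d| + √(posterior var +
  σ²_j/n)): a candidate is penalized both for systematic group-wise
  shifts and for replicate noise. Lowest ρ wins; exact ties break
  alphabetically with a warning.

The trade-off of per-gene absolute-scale biases: a global shift affecting
all candidates in one group (e.g., group-wise loading differences) is
charged to every candidate rather than absorbed, which affects absolute
stability values but hardly the ranking. Missing Ct rows (no
amplification) are dropped, never imputed.

## Dosimetry

The chain is linear: serum mM = brain mM × 1.67 (average serum:brain
ratio from human magnetic-resonance spectroscopy after controlled
intake); serum mg/dL = serum mM × 46.07/10; blood mg/dL = serum mg/dL /
1.24; %BAC = blood mg/dL / 1000, with %BAC defined as grams ethanol per
100 mL blood (w/v) — the definition under which ~269 mg/dL serum ≈ 0.22%
BAC. The brain-water normalization factor for tissue g/L → mM defaults
to 1.0, since 0.68 g/L / 46.07 g/mol ≈ 14.76 mM already matches the
published ~14.8 mM; it stays a config knob. Each conversion is
homogeneous of degree 1, so a `DoseSpec` reconstructs from any one field
(`round_trip`), agreeing within floating-point error; comparisons against
printed reference values carry the rounding of those values (%BAC is
printed to two decimals, so 7 mM brain → 0.0434% prints as 0.04%). One
published parenthetical (70 mM ≈ 1.36 g/L brain, ~0.44% BAC) is
internally inconsistent with the chain itself (70 mM × 46.07 g/mol =
3.22 g/L) and is excluded from the golden values. No time-course
(Widmark-style) pharmacokinetics and no vapor-chamber equilibrium physics
are modeled.

## Statistical routing

Gate order: Shapiro–Wilk per group on raw data; on failure, log-transform
(only if all values are positive) and re-test; if normality is still
violated, route to Kruskal–Wallis. With normality secured, Levene's test
(F type, mean-centered, outliers included) decides between classic ANOVA
and the Brown–Forsythe/Welch route with Dunnett T3. Normality is gated
before variance because the log-transform is specifically the normality
remedy; all tests are two-sided at fixed α = 0.05. Groups too small for
Shapiro–Wilk (n < 3) route nonparametric with a warning. When the log
route is taken, reported group means are back-transformed — i.e.,
geometric means of the raw data. Every gate decision is recorded in the
plan's audit trail.

Test mathematics are delegated where an established implementation
exists: scipy (Shapiro–Wilk, Levene, Kruskal–Wallis, one-way F, Dunnett,
Tukey HSD), statsmodels (two-way OLS/ANOVA, type-II table; identical to
type-I/III on balanced designs), pingouin (Welch ANOVA, Mauchly
sphericity and Greenhouse–Geisser epsilon). Implemented in-module:
the Brown–Forsythe ANOVA for means (F* with Satterthwaite denominator
df) and Dunnett T3 — all pairwise Welch t-tests with Satterthwaite df,
adjusted by the studentized-maximum-modulus bound evaluated under
independence (the Sidak form 1−(1−p)^m), which is slightly conservative
when comparisons share groups. Sidak post hocs after the two-way model
use the pooled residual error; Tukey comparisons run per level of the
first factor across the second. The Mauchly/Greenhouse–Geisser gate is
exposed (`sphericity_gate`) but inert for between-subjects designs,
which is all this package's target designs are.

**Calibration harness.** `simulate_type1` measures each route's
familywise type-I error under its own null: 3 normal groups of n = 3
for ANOVA+Dunnett, a 2×3 design with n = 3 per cell for the interaction
F, a heteroscedastic null (SDs 1/1/5, n = 10) for Welch/BF+T3, and 3
groups of n = 6 for Kruskal–Wallis (where the rank test's discreteness
at smaller n would make it markedly conservative). The acceptance suite
runs 2000 replicates per route and checks the rate lies in [0.03, 0.07]
at α = 0.05. These are small-sample sizes chosen to mirror
triplicate-scale experiments while keeping each family's null exactly
simulable.

## Known limitations

* No object-level segmentation: metrics are pixel-area based, with no
  watershed/instance splitting, no deconvolution, and no correlation-
  based colocalization coefficients beyond the two area ratios.
* The reference-gene selector assumes candidate genes are unrelated in
  their noise; strong co-regulation among candidates would bias the
  deconvolution.
* The router reports conventional degrees of freedom; published analyses
  sometimes print unconventional df for comparable designs, and no
  attempt is made to match those.
* Statistical results on log-routed data are inferences about geometric
  means, not arithmetic ones.
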