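# Methods

This note documents the models implemented in `methregen`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Differential methylation model

For each probe g the beta values (methylation fractions) across the
samples of one study arm are modelled by ordinary least squares,

y_g = X·b_g + e_g,  e_g ~ N(0, σ_g² I),

with design columns: intercept, the BaCl₂-limb indicator (the contrast of
interest), chip/batch dummies, optionally per-animal blocking dummies for
the paired contralateral-limb design, and optionally one latent
unwanted-variation factor. Betas are modelled directly by default; an
M-value (logit₂) option (`use_m_values=True`) is available as a
variance-stabilized alternative. Collinear batch/animal dummies are
pruned automatically (batch can be nested within animals); a rank
deficiency involving the intercept or contrast aborts the fit.

Paired blocking defaults ON: the generator induces a shared per-animal
intercept, and real contralateral-limb designs are paired. Setting
`paired=False` reproduces a plain group+batch covariate model.

### Unwanted-variation factor

The latent factor is the first right singular vector of the row-centered
negative-control-probe submatrix after removing *nuisance* covariate fits
(intercept + batch), unit-norm with its largest-magnitude entry positive.
Two deliberate choices:

* **Controls are not adjusted for the biological contrast.** Projecting
  the limb effect out of the controls before the SVD strips the factor of
  its component along the contrast direction; the factor would then
  shrink residual variances while leaving the confounder's contribution
  to the contrast coefficient untouched, inflating every t-statistic.
  Negative controls are assumed unaffected by the biology, which is what
  licenses estimating the factor without removing it. (We observed the
  inflation directly: with contrast-adjusted controls the null
  false-positive rate at q < 0.05 rose two orders of magnitude.)
* **Control set**: a supplied list when available (the generator records
  its designated controls); otherwise the 1 % least-variable probes after
  removing the nuisance fit.

### Empirical-Bayes moderation

Residual variances are squeezed toward a scaled inverse-chi-square prior
σ_g² ~ d₀·s₀²/χ²_{d₀} by matching the first two moments of log s_g² to
the scaled-F prior predictive: with e_g = log s_g² − ψ(d_g/2) + log(d_g/2),

ψ′(d₀/2) = mean[(e−ē)²·n/(n−1) − ψ′(d_g/2)],  solved by Newton inversion
of the trigamma function, and s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)).

Posterior variances are s̃_g² = (d₀s₀² + d_g s_g²)/(d₀+d_g); the moderated
t uses d₀+d_g degrees of freedom (normal when d₀ = ∞). When the observed
spread of log s² does not exceed its sampling expectation (the moment
equation has no positive solution) or the inversion fails, the estimator
falls back to d₀ = ∞ with the **df-weighted pooled variance** as s₀².
Pooling is used rather than exp(ē) because the latter carries the Jensen
bias of the log transform; in the exactly degenerate case (all s_g²
equal) pooling returns that common value, which is the statistic the
pooled-variance t should use.

Probes with missing values are refitted on their observed subset with
recomputed df; exact fits have their O(machine-eps²) residual snapped to
zero and are excluded from moment matching.

Benjamini–Hochberg correction is delegated to
`statsmodels.stats.multitest` behind a validated wrapper. Significance:
q < 0.05 (configurable). Direction: hypo if effect (BaCl₂ − PBS) < 0,
hyper if > 0; a significant probe with an exactly zero effect is logged
and reported `ns`.

## Regulatory-potential integration

Significant DM CpGs become 1-bp peaks (array CpGs are single-base
features). Gene scores use

RP(g) = Σ over peaks with |pos − tss| ≤ D of exp(−(α + β·|pos−tss|/D)),

α = 0.5, β = 4, D = 100 kb — the classic TSS-decay regulatory-potential
kernel; all three are exposed for sensitivity analysis. Distance is the
strand-agnostic absolute distance from the strand-aware TSS.

Rank products: within each DE direction set (adj p < 0.05, sign of the
log2 fold change), genes are ranked by RP descending and DE p ascending,
with deterministic lexicographic tie-breaking; rank product =
(r_RP·r_DE)/n². A gene is a predicted target if its rank product is at or
below the cutoff (default 0.25) and it has at least one in-window peak.

Direction (activating/repressive) tests compare the RP empirical CDF of
the up- (down-) regulated set against a static background, defined as
genes with DE adj p ≥ 0.5 (the integration's notion of non-differential
genes; configurable). The statistic is D⁺ = sup_x[F_bg(x) − F_set(x)],
positive when the set's RP distribution is shifted upward. With
min(m, n) ≥ 50 the asymptotic one-sided p = exp(−2·D⁺²·mn/(m+n)) is used;
otherwise seeded label permutation with the add-one estimate
p = (1 + #{D⁺_perm ≥ D⁺_obs})/(B+1), B = 9,999 by default.

## Epigenetic clocks

A clock is intercept + sparse probe weights over beta values, with a
gold-median reference value per weighted probe. Probes absent from the
matrix, or missing in a single sample, are imputed with their gold
medians; a weighted probe missing from both the matrix and the reference
is an error. An output-transform slot (identity / log-linear) exists
because published mammalian clocks use calibrated transforms; the default
is identity with ages in weeks. Synthetic clocks are trained by ridge
regression (scikit-learn) with gold medians taken from the training
matrix. Deceleration: 100·(mean_control − mean_treated)/mean_control,
plus the absolute difference in weeks.

## Study-level statistics

Two-way ANOVA with interaction uses Type-I sums of squares for balanced
designs and Type-II otherwise (the arm sizes 11 vs 9 make the real design
unbalanced; the SS convention is recorded in the output). Limbs are
treated as independent observations, matching the original analysis of
the contralateral-limb comparison; a mixed/paired ANOVA is out of scope.
The all-values-equal degenerate case reports F = 0, p = 1. Tukey HSD,
Welch/pooled t-tests and Pearson correlation wrap statsmodels/scipy with
input validation; a from-scratch cell-means decomposition serves as the
ANOVA oracle in the tests.

## Synthetic-data generator

The generator emulates the paired-limb array study: arms YV (young
vehicle, n = 6), OV (old vehicle, n = 11), OS (old senolytic, n = 9),
each animal contributing PBS and BaCl₂ limbs (52 samples); 2,000 genes ×
8 probes (2 promoter, 2 exon, 2 intron, 1 five-prime and 1 three-prime
UTR) ≈ 16,000 annotated probes, plus 200 intergenic negative-control
probes and 30 clock CpGs. Acceptance and test runs scale n_genes down
(120–1,000) to keep the full chain in seconds; the structure is identical.

Per-probe baselines are drawn from feature-class-specific Beta
distributions (promoters/5′UTRs low, gene bodies high; promoter
Beta(2.5, 5) keeps baselines far enough from the floor that a −0.2 shift
stays inside the unit interval). Sample values are assembled on the logit
scale — injury shift on responsive promoter CpGs (calibrated so the
noiseless beta-scale shift equals `delta_beta`), an extra senolytic term
in the OS arm, a per-chip batch effect, one latent factor with per-probe
loadings, a shared per-animal intercept and residual noise — and mapped
through the inverse logit, so betas stay in [0, 1] without clipping
artifacts. Injury-responsive CpGs are selected gene-wise (all promoter
probes of an `effect_fraction` share of genes) so that expression
coupling acts on whole promoters.

Clock CpGs carry a linear-in-beta age trend (slope ±0.002 per week,
baselines placed so trajectories stay inside [0.05, 0.95]); the emitted
generative ClockModel is the exact least-squares inverse of that trend,
so a noiseless study inverts to machine precision. Old BaCl₂ limbs have
their effective age pulled toward the young mean by the rejuvenation
factor ρ (default 0.5); per-animal biological-age jitter (SD 2 weeks) and
beta-scale clock noise (SD 0.02) are separate from the array noise.

RNA-seq counts are negative binomial (variance μ + αμ², α = 0.05) around
per-gene log2 baselines ~ N(6, 1.5) scaled by uniform library factors;
for coupled genes (half of the responsive genes) the log2 mean gains
γ·(baseline − observed promoter beta), γ = 4, so hypomethylation drives
up-regulation. Leaving the other half of responsive genes uncoupled is
deliberate: it puts peak-bearing genes into the static background, which
keeps the repressive (down) direction test honest — a spurious down set
is compared against a background that also contains peaks.

The internal DE test (`emit_de_table`) regresses log2 normalized counts
(median-of-ratios size factors — raw library totals are biased when 5–10 %
of genes move in one direction) on the group indicator with the same
moderated-t engine, after excluding all-zero genes and independent
filtering of weakly expressed genes (mean count < 10): without precision
weights, the log-scale variance of near-zero counts is badly behaved and
testing them costs calibration and power.

**What the generator does not emulate**: probe-level detection p-values,
cross-reactive or off-target probes, sex chromosomes, beta-value
bimodality beyond the feature-class baselines, mean-variance trends of
real arrays, read-level RNA-seq structure, or the published clocks'
calibrated output transforms. Passing tests therefore demonstrate the
*statistical machinery* — recovery of planted effects under the assumed
noise model, type-I control, calibration of the permutation tests, clock
invertibility — not fidelity to any particular real dataset.

## Numerical and reproducibility choices

* All internal coordinates 0-based half-open; 1-based fields (manifest
  positions, TSS, peak positions) converted at the I/O boundary only.
* Trigamma inversion: Newton with the limma-style update, tolerance
  1e-10; closed-form guards for extreme arguments.
* Permutation tests use the add-one p estimate and a mandatory seed.
* The pipeline expands its single global seed into per-stage seeds with
  `numpy.random.SeedSequence(seed).spawn` in a fixed stage order
  (simulate, de, direction_test), so stages stay individually
  reproducible; identical configs give byte-identical TSV/JSON outputs.
* Beta matrices are written at %.17g, so write/read round-trips are exact
  to double precision.

## Known limitations

* The moderated t on beta values inherits the bounded-support
  heteroscedasticity of beta-distributed data; the M-value option
  mitigates but changes the effect scale.
* One latent factor (k = 1) only, matching the single-vector adjustment
  the pipeline targets.
* The asymptotic one-sided KS p-value ignores ties in the RP
  distribution (many zeros in sparse-peak backgrounds); the permutation
  path is exact under exchangeability and is used automatically for
  small sets.
* `emit_de_table` is a closed-loop stand-in for a count-based DE tool; it
  is deliberately simple (no dispersion shrinkage across genes on the
  count scale, no precision weights).
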