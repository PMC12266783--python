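# methregen

Methylome–transcriptome integration and epigenetic-clock analysis for
regenerating skeletal muscle methylation arrays.

## The problem

Severe muscle injury (intramuscular BaCl₂) triggers degeneration and then
stem-cell-driven regeneration. Profiling DNA methylation of the regenerated
muscle against the contralateral PBS-injected control limb asks three
questions this package answers computationally:

1. **Which CpGs change?** Per-probe linear models on normalized beta values
   (methylation fractions in [0, 1]) with chip/batch covariates, a latent
   unwanted-variation factor estimated from negative-control probes,
   empirical-Bayes variance moderation, and Benjamini–Hochberg FDR control.
   A probe is differentially methylated (DM) at q < 0.05; hypo- vs
   hypermethylated by the sign of the BaCl₂ − PBS effect.
2. **Which genes do those CpGs regulate?** Significant DM CpGs become
   single-bp "methylation peaks". Each gene g is scored by a TSS-distance
   regulatory potential

   ```
   RP(g) = Σ_peaks, |d| ≤ D   exp(−(α + β·|d|/D)),   α = 0.5, β = 4, D = 100 kb
   ```

   where d is the peak's distance from the strand-aware TSS. Within each
   differential-expression direction set, genes are ranked by RP and by DE
   p-value, and the rank product (r_RP·r_DE)/n² orders candidate
   epigenetically regulated targets. Whether methylation acts as activating
   or repressive is tested by a one-sided two-sample KS comparison of the RP
   distribution of up- (down-) regulated genes against non-differential
   background genes, asymptotically or by seeded label permutation.
3. **Does regeneration rejuvenate the methylome?** Epigenetic clocks —
   sparse linear predictors DNAmAGE = intercept + Σ wⱼβⱼ with gold-median
   imputation of missing probes — are applied per sample; age deceleration
   is summarized as 100·(mean_control − mean_treated)/mean_control and
   tested by two-way ANOVA (treatment × injury) with Tukey post-hoc
   comparisons.

Everything is driven end-to-end by a synthetic-study generator
(`methregen.simulate`) that emulates the paired contralateral-limb design
(young-vehicle, old-vehicle, old-senolytic arms; logit-scale injury,
batch, latent-factor and noise components; age-trending clock CpGs with a
tunable rejuvenation factor; negative-binomial RNA-seq counts coupled to
promoter methylation loss), so every stage is verifiable without any
external download.

## Worked example

```python
from methregen import (SimulationConfig, simulate_study, DifferentialMethylation,
                       peaks_from_dm, score_genes, direction_test, emit_de_table,
                       apply_clock, percent_deceleration)

study = simulate_study(SimulationConfig(seed=3, n_genes=1000,
                                        n_animals={"YV": 0, "OV": 10, "OS": 0}))
res = DifferentialMethylation.from_study(
    study.beta, study.sheet, arm="OV", manifest=study.manifest,
    ruv=True, control_probes=study.truth.control_probes).fit()
print(res.summary())
```

```
Differential methylation (moderated t)
==========================================
probes:            8230
samples:           20
design columns:    14
scale:             beta
prior df (d0):     6.125
prior var (s0^2):  0.00074382
q < 0.05:          229 (209 hypo, 20 hyper)
```

200 promoter CpGs carry a planted −0.2 beta shift in the injured limb; the
model recovers 209 hypomethylated calls (the planted probes plus a handful
of false positives) out of 8,230 probes. Continuing the chain:

```python
peaks = peaks_from_dm(res.records, study.manifest)
rp = score_genes(study.genes, peaks)
de = emit_de_table(study.counts, study.sheet, arm="OV")
up = direction_test(rp, de, "up", seed=1)
print(f"activating-function test: D+ = {up.d_plus:.3f}, p = {up.p:.4g}")

ages = apply_clock(study.beta, study.clock).merge(study.sheet, on="sample_id")
pbs = ages.query("limb == 'PBS'")["dnam_age"].mean()
ba  = ages.query("limb == 'BaCl2'")["dnam_age"].mean()
dec = percent_deceleration(pbs, ba)
print(f"DNAmAGE {pbs:.1f} -> {ba:.1f} weeks: {dec.percent:.0f}% decelerated")
```

```
activating-function test: D+ = 0.920, p = 0.0001
DNAmAGE 104.7 -> 63.9 weeks: 39% decelerated
```

Hypomethylation peaks sit at the promoters of up-regulated genes, so the
up-set's regulatory-potential CDF dominates the background (small p); the
generative clock reads the injured limbs as decelerated because the
simulator rejuvenates old BaCl₂ limbs halfway back to the young mean.

A command-line interface mirrors the library:

```bash
methregen simulate --seed 3 --outdir study/
methregen diffmeth --beta study/beta.tsv --sheet study/sheet.tsv \
    --manifest study/manifest.tsv --contrast OV --ruv --out dm.tsv
methregen run --config run.yaml --outdir out/
```

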