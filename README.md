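# clockscope

Assessing circadian clock health in population-level gene expression data
when sample collection times are unknown.

Human tissue cohorts (biopsies, surgical specimens, tumor atlases) are
snapshots: every sample was taken at some unknown internal circadian phase.
Differential expression of clock genes between conditions says little about
whether the clock *works*. `clockscope` implements the complementary
statistics that do, for bioinformaticians analyzing bulk expression matrices:

- **nCV** — a gene's coefficient of variation across samples divided by the
  mean CV of all genes in the dataset. In phase-scrambled population data,
  oscillation shows up as excess cross-sample variance, so core-clock nCV is
  a surrogate for relative oscillation amplitude (rAMP): high when the clock
  is intact, collapsed when it is disrupted.
- **Clock correlation + Mantel z** — the Spearman correlation matrix over a
  core-clock gene set (activators correlate positively with each other,
  negatively with repressors), compared against a reference matrix via a
  Mantel permutation test. The z-statistic locates the observed
  triangle-correlation within the permutation null; higher z = better
  preserved clock network.
- **CYCLOPS-style ordering** — an autoencoder with a unit-circle bottleneck
  fitted to eigengenes of rhythmic seed genes, assigning each sample a
  latent circadian phase θ̂ ∈ [0, 2π). Ordering significance requires both
  Met<sup>smooth</sup> < 1 (the circular trajectory through eigengene space
  is smoother than a linear PC1 ordering) and Stat<sup>err</sup> < 0.05 (a
  permutation p-value comparing the circular fit to a 1-D linear-bottleneck
  fit against per-gene phase-scrambled nulls).
- **Cosinor rhythmometry** — x = M + A·cos(θ − φ) per gene on the ordered
  samples; a gene is rhythmic when p < 0.05, rAMP = A/M > 0.1, R² > 0.1 and
  fitmean M > 16 (all strict; a stricter p < 0.01 preset is included for
  reordered time-stamped designs).
- **PSEA** — phase set enrichment: Kuiper-statistic Monte-Carlo test of
  whether a gene set's acrophases cluster at a common circadian time.
- **Synthetic cohorts** — a generator producing population or time-stamped
  matrices with known latent phases, per-gene mesor/rAMP/acrophase, a
  disruption factor that jointly suppresses amplitude and decoheres phase,
  multiplicative noise and batch effects, so every stage is testable against
  ground truth.

## Worked example

```python
import dataclasses
from clockscope import (SimConfig, simulate_population, compute_ncv,
                        clock_correlation_matrix, load_reference_correlation,
                        mantel_compare)

cfg = SimConfig(n_samples=200, n_genes=300, n_background_rhythmic=43,
                background_ramp_range=(0.15, 1.0), noise_cv=0.2, seed=1)
intact = simulate_population(cfg)
tumor = simulate_population(dataclasses.replace(cfg, disruption=0.9))

for label, ds in [("intact", intact), ("disrupted", tumor)]:
    ncv = compute_ncv(ds.matrix)
    cmp = mantel_compare(clock_correlation_matrix(ds.matrix),
                         load_reference_correlation(),
                         n_permutations=1000, seed=0)
    print(f"{label}: mean clock nCV = {ncv.mean_ncv:.2f}, "
          f"Mantel z = {cmp.z_stat:.1f}, p = {cmp.p_value:.4f}")
```

prints

```
intact: mean clock nCV = 2.16, Mantel z = 11.2, p = 0.0010
disrupted: mean clock nCV = 1.02, Mantel z = 4.1, p = 0.0010
```

The intact cohort shows high clock-gene nCV and a correlation matrix far
into the preserved tail of the Mantel null; disruption collapses the nCV
toward 1 (clock genes no more variable than the background transcriptome)
and cuts the z-statistic to a third. Ordering the intact cohort with
`select_seed_genes` → `compute_eigengenes` → `fit_cyclops` → `stat_err`
recovers the latent phases (circular correlation ≈ 0.99 against the
generative truth, Met^smooth ≈ 0.5, Stat^err = 0.025), while a fully
disrupted cohort is not orderable (Stat^err ≈ 0.7).

The same workflow is available from the shell:

```
clockscope simulate --config sim.yaml --outdir data/
clockscope ncv --expression data/expression.tsv --out ncv.tsv
clockscope cyclops --expression data/expression.tsv --seed 1 --out phases.tsv
clockscope run --config pipeline.yaml --outdir results/
```

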