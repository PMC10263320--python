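# Methods

## The problem

Population-level expression cohorts sample each subject at one unknown
circadian phase. If the tissue clock is running, core clock genes oscillate
coherently, which leaves three population-level fingerprints: excess
cross-sample variance in clock genes (captured by nCV), a stereotyped
correlation structure among clock genes (captured by the clock correlation
matrix), and a one-dimensional circular manifold in the expression of
rhythmic genes (recoverable by circular ordering). `clockscope` measures all
three and then treats the recovered ordering as a pseudo-time axis for
cosinor rhythmometry and phase set enrichment.

## Synthetic cohorts

The generator draws, for sample s and gene g,

    x_gs = m_g · (1 + (1−δ)·A_g·cos(θ_s + ε_gs − φ_g)) · η_gs

- θ_s — latent phase, uniform on [0, 2π) or restricted to a circular window
  (rejection sampling), emulating daytime-only specimen collection.
- m_g > 0 — mesor in linear expression units; A_g ∈ [0, 1.5] — relative
  amplitude; φ_g — acrophase.
- δ ∈ [0, 1] — disruption. It both scales amplitudes by (1−δ) and inflates
  the per-observation phase jitter ε_gs ~ N(0, (κ⁻¹(1+2δ))²), so that
  disruption degrades relative amplitude *and* cross-gene correlation
  jointly, which is the empirical signature of a broken clock. The
  decoherence multiplier 2 is a fixed package constant.
- η_gs — multiplicative log-normal noise with unit mean and linear-scale
  CV σ (log-SD √log(1+σ²)); keeps values non-negative and mimics RNA-seq
  abundance noise. Negative oscillation troughs (possible only when
  (1−δ)A_g > 1) are clipped at zero.
- Batches: per-sample multiplicative factor e^offset by batch label.

The default 17-gene clock map anchors ARNTL at phase 0, places NPAS2/CLOCK
with it, the ROR/REV-ERB loop and PAR-bZip outputs (NR1D1/2, DBP, TEF, HLF)
in mid-cycle, and the repressors (PER1-3, CRY1/2, BHLHE40/41) roughly in
antiphase, with CRY1/RORC/NFIL3 trailing late. The phases are canonical
mammalian clock geometry, documented constants rather than estimates from
any dataset. Map amplitudes are capped at 1 so defaults never clip.
Background rhythmic genes get uniform random acrophases and amplitudes
(default range 0.1–1.0 in population defaults; the ordering test condition
uses 0.15–1.0), and mesors log-normal around 50 units.

Time-stamped designs convert collection time to phase by
θ = 2π·(t mod 24)/24 — a fixed 24 h period is assumed throughout.

What the generator does *not* emulate: count-level sampling noise and
library-size variation, gene-gene co-regulation beyond the shared circadian
phase, cellular-composition differences, and the long-tailed
between-subject variability of real tumors. Passing tests therefore show
that the statistics behave correctly when their generative assumptions
hold, not that any particular human dataset satisfies those assumptions.

## nCV and clock correlation

CV uses the population (1/n) standard deviation; the convention is applied
uniformly so the nCV ratio is internally consistent. The nCV denominator is
the mean CV over *all* genes surviving the caller's filtering, per its
definition; the filtering state therefore matters and is logged by the
pipeline. Group comparison of per-gene nCV is a paired two-sided t-test
across genes (Wilcoxon optional); identical inputs return p = 1 by contract.

The clock correlation matrix is Spearman (average ranks) over a 17-gene
set; zero-variance genes are assigned 0 correlation rather than NaN so that
fully flattened cohorts remain analyzable. The Mantel statistic is the
Pearson correlation of the two upper off-diagonal triangles; the null
jointly permutes row/column labels of the reference; the test is one-sided
(greater) because "closer to the reference" is directional. z uses the
population SD of the permutation null; with the default 10,000 permutations
z is stable to roughly two decimals. The packaged reference matrix is
derived from a large intact low-noise simulation (n = 2000, noise CV 0.05,
fixed seed) and is user-replaceable by any labeled square TSV.

## Ordering

Seed genes are screened for mean expression ≥ 1 unit and CV within
[0.05, 2.0] (broad enough to keep designed rhythmic genes, excluding flat
and pathological rows), then scaled to relative expression (x − mean)/mean,
which removes per-gene scale exactly. Eigengenes are the SVD scores of the
scaled matrix; the default k is the smallest k ≥ 2 reaching 85% cumulative
variance, capped at 10. An optional oscillation screen scores component
pairs by ring structure (1 − var(r)/mean(r)² of the per-sample radius,
threshold 0.5) and restricts to pair components when any pair qualifies.

The circular autoencoder is linear k→2, division by the Euclidean norm
(projection onto the unit circle), linear 2→k, minimizing mean squared
reconstruction error. Training is full-batch gradient descent with a
per-restart adaptive step: a step is accepted only if the loss decreases,
otherwise the step size halves (growing 1.1× on acceptance). This makes the
loss sequence provably non-increasing within each restart and removes the
need to tune a learning rate to the data scale (scores are globally scaled
to unit RMS for conditioning — a scalar, so component weighting is
unchanged). Defaults: 40 restarts, 2000 epochs, early stop at relative
improvement < 1e-8. Ties between equal-loss restarts resolve to the lowest
restart index. Phases are atan2 of the bottleneck activations of the best
restart. With fewer than ~200 samples the fit warns: phase coverage of the
circle becomes incomplete well before the math breaks (hard floor 30).

Met^smooth: mean consecutive-step length of the eigengene trajectory
visited in circular-phase order (closed tour, n steps) divided by the same
under a PC1 ordering (open path, n−1 steps); < 1 favors the circular
ordering.

Stat^err: F = ((RSS_lin − RSS_circ)/1)/(RSS_circ/(n(k−2))), where RSS_lin
is the exact optimum of the 1-D linear-bottleneck autoencoder (the rank-1
PCA reconstruction, computed in closed form — the global optimum of that
architecture, so no optimizer noise enters the comparator). The denominator
df degenerates at k = 2 and is floored at 1; since the statistic is only
compared against its own permutation null, the constant does not affect p.
The null permutes each seed gene's values independently across samples
(preserving marginals, destroying cross-gene coherence), recomputes the
decomposition with the observed k, and refits the circular model (default
39 nulls × 10 restarts); p = (#{F_null ≥ F_obs}+1)/(n_null+1). The minimal
attainable p with 39 nulls is 0.025, below the 0.05 criterion. A cohort is
"significantly ordered" only when Met^smooth < 1 AND Stat^err < 0.05.

A learned circular coordinate is identified only up to rotation and
reflection. Reported phases are aligned by setting the anchor gene's
(default ARNTL) fitted acrophase to 0 and choosing the direction in which
PER1 lags ARNTL by less than half a cycle. Agreement with known
phases/times is quantified by the Fisher–Lee circular correlation (with the
optimal reflection) and the median absolute circular error after optimal
rotation.

## Rhythmometry and enrichment

Cosinor fits are closed-form least squares on {1, cos θ, sin θ}; p is the
F-test of the harmonic pair against the intercept-only model (2 and n−3
df). Constant genes return amplitude 0, p 1 by contract so transcriptome
scans never abort. Rhythmicity requires all four strict inequalities —
p < 0.05, rAMP > 0.1, R² > 0.1, fitmean > 16 (`human_default`); the
`mouse_reorder` preset tightens p to < 0.01. The fitmean threshold is in
linear expression units and configurable, since expression units are
dataset-dependent.

PSEA computes the Kuiper statistic of a set's acrophases against the
uniform circular CDF and calibrates it by Monte Carlo draws from the chosen
background — uniform, or resampling from all rhythmic-gene phases (the
latter tests clustering *beyond* the transcriptome-wide phase
distribution). Defaults: domain 24 h, min 10 members, 10,000 simulations,
BH correction across sets.

The time-stamped test is the same cosinor on θ = 2π(t mod 24)/24 with
BH-FDR across genes; rhythmic iff q < 0.05 and rAMP > 0.1.

## Pipeline and problem sizes

The pipeline spawns independent per-stage seeds from one global seed via
`numpy.random.SeedSequence`, so a config + seed reproduces every number.
Reports are schema-validated JSON plus TSV tables; rhythm results are
flagged (not suppressed) when the ordering criteria fail.

Test and acceptance runs use desk-scale cohorts chosen to exercise every
code path with stable statistics: 200 samples × 300 genes with 60 rhythmic
seed genes for ordering, 100-sample cohorts for nCV/Mantel contrasts,
36-sample (every 4 h × 48 h × 3) time-stamped designs, and 500–1000 genes
for FDR calibration. These sizes give reproducible pass/fail behavior for
the seeded statistical checks while keeping a full run on one CPU in the
minutes range.

## Known limitations

- The reference correlation matrix is simulation-derived; applying the
  Mantel comparison to real data should use a tissue-appropriate empirical
  reference.
- The period is fixed at 24 h everywhere; no period estimation.
- The linear-vs-circular F statistic is an operationalization of a nested
  model comparison, not a calibrated F distribution — its validity comes
  entirely from the permutation null.
- Gene identity is symbol-based; only a small clock-gene alias table is
  applied (no genome-wide ortholog mapping).
- The oscillation screen is a radial-structure heuristic, not a full
  paired-sinusoid search.
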