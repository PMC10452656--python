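# Methods

## The model

A *stochastic epimutation* (SEM) at a CpG probe in one sample is an extreme
outlier of that probe's methylation distribution across the cohort.  Working
on the M scale (M = log2 β/(1−β), approximately homoscedastic), the cohort
distribution of each probe defines Tukey-style outer fences

    Lmin = Q1 − 3·IQR,        Lmax = Q3 + 3·IQR,

with Q1, Q3 the first and third quartiles over **all** samples of the dataset
(the tested sample is not excluded) and IQR = Q3 − Q1.  A value strictly
beyond a fence is an epimutation — hypermethylated above Lmax, hypomethylated
below Lmin — and its *delta* is the distance to the violated fence.  Values
at a fence are not calls (the interval is read as closed); the comparison is
configurable.

Deltas are pooled over all calls of a dataset, separately per direction, and
split by their own quartiles into four weight classes:

    rank 1: δ ≤ q25,  rank 2: q25 < δ ≤ q50,  rank 3: q50 < δ ≤ q75,  rank 4: δ > q75.

The *weighted stochastic epimutation score* (WSEMS) of a sample for a
(gene, region, direction) cell is the sum of the weights of its calls on
probes annotated to that gene region (regions: TSS1500, TSS200, 1stExon,
Body, from the Illumina manifest dialect; a multi-annotated probe counts
fully toward every annotated pair).  Quartile weighting expresses each
deviation relative to the dataset's own delta distribution, which absorbs
dataset-level scale differences; datasets are never pooled before ranking.

## Association

Per gene within one (region, direction) stratum:

    wsems ~ group + age + stage + epithelial     (quantile regression, τ = 0.5)

with stage coded 1–4 as a single ordinal slope and optional covariates
dropped when absent.  The group coefficient is the covariate-adjusted shift
of the median burden in the positive group.  The model is oriented with the
burden as the outcome; a binary outcome in a median regression would be
ill-posed, and only this orientation gives the coefficient its intended
reading.

**Inference.**  The outcome is a zero-inflated integer score with heavy ties
at the median, so asymptotic rank-score inference is fragile.  The p-value
of the group coefficient comes from a seeded xy-pair bootstrap (default
B = 500):

    p = min(1, 2·min(#{b* ≤ 0}+1, #{b* ≥ 0}+1) / (B+1)).

Replicates whose exact solution is 0 count toward both tails, so effects
invisible at the median yield p ≈ 1.  Every refit is solved **exactly**: a
pair-bootstrap replicate is the original problem with integer observation
weights, and the weighted-LAD dual (max y'e s.t. X'e = 0, |e_i| ≤ w_i/2)
differs between replicates only in variable bounds, so one LP model per gene
is re-solved with a warm simplex basis per replicate.  Smooth IRLS-style
approximations were rejected: on tied integer outcomes they stall with a
systematic bias toward their initialisation, which corrupts sign counts.
Ties at the optimum are resolved by the LP vertex; the solver convention is
recorded in the output metadata.  Sampling stops early once both sign counts
reach 25 (the p-value is then ≳ 0.1 and can only grow); the reported p uses
the replicates actually drawn, a sequential Monte Carlo p-value that is at
most conservative.

The Monte Carlo resolution matters jointly with multiplicity: the p floor
2/(B+1) must sit below the Benjamini–Hochberg granularity α·k/m of the
stratum.  For the 100-gene validation studies the recovery analyses use
B = 1000 (floor 0.002); the package default stays B = 500.

BH adjustment is applied within one (region, direction) stratum; genes with
all-zero scores are reported as untestable and excluded from the family.

## Enrichment

Significant genes (BH q < 0.05 by default) are tested against GMT gene sets
with the one-sided hypergeometric upper tail, conditioning on the universe
of genes actually tested in the stratum.  The single-list ORA is repeated
over seeded 90% subsamples of the significant list (default 10 iterations);
per pathway the lowest/highest adjusted p over iterations and the fraction
of significant iterations (occurrence) are reported, and pathways below 0.9
occurrence are dropped.  This subsampling scheme reproduces the
iteration/occurrence semantics of network-based enrichment tools without
their external interaction network; that substitution is recorded in output
metadata.  The per-pathway coefficient is the mean group coefficient of the
pathway's significant member genes (rule recorded in metadata; no standard
exists).  Pathway tables from several cohorts are intersected on set ID.

## Synthetic cohorts

The generator emulates the statistical shape the analysis assumes, not any
real accession:

- **Betas**: per-probe baseline mean from a 3-component beta mixture
  (weights 0.45/0.10/0.45; shapes (2,18)/(5,5)/(18,2): unmethylated,
  intermediate, methylated classes); within-probe values beta-distributed
  around the mean with concentration 50 (typical array-like spread).
- **Covariates**: group positive/negative at prevalence 0.8; age ~
  N(57.65, 12.74²) clipped to [18, 95]; stage I–IV with probabilities
  (0.20, 0.55, 0.20, 0.05); epithelial fraction ~ Beta(14, 6) (mean 0.7).
  Covariates are independent of the methylation values; the PCA diagnostic
  is validated on purpose-built matrices instead.
- **Planted outliers**: per-(probe, sample) Bernoulli at base rate 0.02 —
  the elevated SEM burden of tumour methylomes, not healthy tissue — placed
  on the M scale at Q3 + d·IQR (hyper) or Q1 − d·IQR (hypo) of the probe's
  baseline distribution, d ~ U(5, 12), then transformed back to betas.
  The lower bound is deliberately above the contractual minimum of 4: at
  contaminated signal probes (rate 0.16 under multiplier 8) the empirical
  Q3 and IQR inflate enough that a 4·IQR displacement lands inside the
  recomputed fences in up to ~60% of probes, whereas ≥5·IQR keeps planted
  calls recoverable by construction.  Every planted call is recorded in a
  truth table.
- **Signal genes**: listed (gene, region, direction) cells whose probes get
  the base rate times a multiplier (default 8) in the affected group only.
  Detectability at the median requires the affected group's probability of
  a nonzero region score, 1 − (1 − 8·rate)^k, to clear 0.5 comfortably;
  with the deterministic region layout (TSS1500 takes 35% of each gene's
  probe block, k = 7 at the default 20 probes/gene) it is ≈ 0.7.
- **Annotation / gene sets**: annotation is a pure function of the shape
  parameters (shared across seeds); the first gene set is the designated
  signal pathway (all signal genes plus random padding) so enrichment
  recovery is checkable.

What the generator does **not** emulate: Infinium I/II chemistry and
normalization artefacts, batch effects, chromosomal autocorrelation,
covariate–methylation coupling, cell-type mixture signals.  Passing
recovery tests therefore demonstrates the pipeline's statistical behaviour
under its own assumptions, not performance on real arrays.

## Numerical conventions

- Quantiles: linear interpolation between order statistics at p·(n−1)
  (numpy default), recorded in output metadata; the quartile convention of
  the original implementation is not documented anywhere, so ours is simply
  fixed and logged.
- Fences use strict inequalities; a constant probe (IQR = 0) calls only
  values different from the constant.
- Betas are clipped to [1e-6, 1−1e-6] before the logit; probes with fewer
  than 4 non-missing values are skipped with a warning.
- Probe QC: detection-p and bead-count grids are optional (public beta
  matrices often arrive pre-QC'd); absent grids skip those rules and the
  removal report records which rules applied.  Sample loss uses a strict
  \>10% comparison.  Sex-chromosome probes are retained.
- Degenerate designs (one group) and misaligned inputs raise; they are
  never silently coerced.

## Validation scale

The recovery and calibration studies run at 200 samples × 2,000 probes ×
100 genes per cohort with ten signal genes at multiplier 8 — large enough
that binomial noise on group medians is small relative to the planted
effect, small enough for routine re-runs.  Full array-scale cohorts
(25k–450k probes, hundreds of samples) exercise identical code paths; all
per-probe and per-gene operations are vectorised or linear in the data.

## Known limitations

- The bootstrap p-value floor 2/(B+1) bounds attainable BH q-values; very
  large strata need proportionally larger B.
- Median regression cannot see group effects that leave the group medians
  equal (e.g. burden concentrated in < 50% of carriers); this is a property
  of the published score's inference choice, preserved deliberately.
- Occurrence from subsampling measures stability of the gene list, not the
  topology-aware iteration of network-based tools.
- The LP vertex convention makes tied-coefficient values deterministic per
  solver; across different LP solvers a tie may resolve differently.
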