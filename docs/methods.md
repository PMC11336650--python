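# Methods

This note documents the models, defaults and numerical choices behind
`twaskit`, and what the synthetic-data generator does and does not
emulate.

## The synthetic study generator

The generator produces every pipeline input as a pure function of
`(SimConfig, seed)`; identical seeds give byte-identical outputs.  Each
stage draws from its own fixed sub-stream (`numpy` `SeedSequence` spawn
keys), so adding a stage never perturbs earlier stages' draws.

**Gene map.** Genes are laid out in correlation blocks of `block_size`
genes (default 5).  Each block spans strictly less than one `window_bp`
window (default 500 kb) and consecutive blocks are separated by more than
a window, so the block structure and the windowing rule coincide exactly —
cross-block gene pairs can never be "within window".  This idealisation
makes window-related properties provable by construction; real gene maps
have overlapping, unevenly spaced correlation neighbourhoods.

**TWAS summary statistics.** Each gene appears in every panel under both a
FUSION-style and an SMR-style method stream.  `n_signal_genes` (default
50 of 1000) carry a true Z with |Z| ~ N(`signal_z_mean` = 6, 1) and a
random, panel-consistent sign; panel records add unit normal noise; null
genes are N(0, 1).  Two-sided p-values are computed exactly from the
normal tail of Z.  Colocalisation posteriors are Beta(20, 2) (PP4, signal)
vs Beta(2, 20) (null), with PP3 a uniform fraction of the remaining mass;
HEIDI p-values are uniform for signal genes and skewed small
(Beta(1, 30)) for half the null genes (`null_heidi_small_frac` = 0.5).
Record noise is independent across the two method streams, which is
pessimistic (real FUSION and SMR Z-scores on the same panel are highly
correlated) and slightly inflates the number of independent chances a null
gene gets in triage.

**Feature correlation.** Gene×panel features correlate `cross_panel_r`
(default 0.9, not 1, to keep blocks positive definite) for the same gene
across panels and `within_block_r` (default 0.5) between block-mates.
The block template's positive semi-definiteness is checked by
eigendecomposition and violating parameter choices are rejected.

**Case-control cohorts (liability-threshold model).**  Individual
liability is `c·S + e` with `S = Σ_g w_g z_ig` the true weighted
expression score, `e ~ N(0,1)`, and `c` solving
`c²Var(S)/(c²Var(S)+1) = target_liability_r2` (default 0.05).  A case is
anyone whose standardized liability exceeds `Φ⁻¹(1−K)` with `K = 1/300`,
so the pre-ascertainment case fraction is exactly K; cases are then
oversampled to `n_cases` (default 2000 + 2000 controls per platform, two
platforms).  Sampling is implemented by exact Gaussian conditioning: the
scalar pair `(S, e)` is drawn for the whole rejection pool, and the full
expression vector is drawn only for accepted individuals, conditional on
their score (`z = z0 + Σw (s − w'z0)/Var(S)` with `z0` an unconditional
draw).  This is distributionally identical to drawing expression first and
keeps small-prevalence ascertainment cheap.  Ascertainment never alters an
individual's phenotype, only which individuals are sampled.

Within cases, onset site, onset age and survival depend linearly on the
standardized true score (defaults: +0.4 latent-probit units for spinal
onset, +2 years onset age per SD, −4 months survival per SD, with 10- and
12-unit residual SDs around means of 60 years and 36 months).  Survival
is uncensored and its unit is a config label (`survival_units`,
default months); the upstream analysis treats survival by linear
regression, so no event-time machinery is modelled.  Each platform
applies a small global intensity shift and drops a disjoint 10 % of genes
(`platform_dropout`), exercising missing-gene handling in scoring.

**Drug database.**  200 drugs with Poisson(8)-sized gene sets (≥ 2) and
labels from the closed vocabulary (three "decrease", two "increase", one
undirected).  Ten planted protective drugs draw ~80 % of their genes from
signal genes with code `−sign(true Z)` (the drug opposes the risk
direction) and share one ATC level-3 class; optional deleterious drugs are
anti-aligned in a second class.  Null drugs get random genes, codes and
ATC classes.

**What passing tests do not show.**  The generator has no batch effects,
no probe-level noise structure, no covariate confounding (sex has no true
effect), no LD beyond the idealised block correlation, uniform effect-size
distribution across signal genes, and expression measured pre-treatment.
Recovery of planted parameters here demonstrates the estimators are
consistent with their own generative model, not that real cohorts are this
well behaved.

## Triage

Both colocalisation boundaries are strict, exactly as printed in the
criteria (`PP4/(PP3+PP4) > 0.8`, HEIDI `p > 0.05`); a zero posterior mass
(`PP3+PP4 = 0`) is "not evaluable", deliberately distinct from False.
BH-FDR is applied per method stream across all panels; expression and
protein records are pooled within a stream by default with
`separate_molecules` exposing the alternative, since the upstream
correction is specified per method only.  Credible-set containment
defaults to the gene body (`window_bp = 0`), configurable.  Gene-level
association streams without direction (MAGMA-style) are intentionally not
a high-confidence criterion.

## PTS construction

Clumping is greedy: sort by p ascending (ties broken lexicographically on
feature id for determinism), take the next unremoved feature as lead,
remove everything with `r² > 0.1` against it.  Features pool across
panels in a single pass; Z-averaging per gene happens strictly after
clumping.  Weight building defaults to the FUSION-style record stream so
each gene@panel feature enters once; passing `methods=None` keeps all
records with the smallest-p row per feature.  Missing correlation entries
mean r = 0 (beyond-window features are independent by construction).
Expression is standardized per gene with the sample SD (n−1) over the
whole cohort, cases and controls together; genes in a weight set but
absent from a platform are skipped, never imputed.  The default threshold
grid is {1e−6, 1e−5, 1e−4, 1e−3, 0.01, 0.05, 0.1, 0.5, 1}.

## Association evaluation

The reported variance explained is the incremental R² of the full OLS
model (intercept, sex, PTS) over the sex-only model — the standard choice
in the polygenic-score literature the PTS imitates.  The liability
conversion is the Lee et al. (2012) ascertainment-corrected
transformation; with `t = Φ⁻¹(1−K)`, `z = φ(t)`, `m = z/K`,
`C = [K(1−K)]²/[z²P(1−P)]`, `θ = m(P−K)/(1−K)·(m(P−K)/(1−K) − t)`, the
result is `C·R²/(1 + CθR²)`.  K is 1/300 for case-control and a nominal
0.5 for onset site; P is always the realized case proportion of the
analysis sample.  Meta-analysis is fixed-effect IVW; the meta-level R² is
the `t²/(t²+df)` approximation from the meta Z and pooled residual df,
and best-threshold reporting takes the in-sample maximum over the grid
with no out-of-sample correction — an optimism both flagged in the output
header and shared by the upstream reporting convention.  Survival is
analysed by linear regression, not proportional hazards, matching the
upstream design.

## Drug and ATC enrichment

The signed statistic is a standardized concordance under the permutation
null that reassigns the drug's codes to random measured genes.  Closed
form: `E[S] = μ_Z Σc`, `Var[S] = σ²_N[Σc² − ((Σc)² − Σc²)/(N−1)]`
(sampling without replacement from the N-gene universe).  Drugs with ≤ 8
directional genes are evaluated under the permutation null itself — exact
enumeration when the assignment space is ≤ 50 000, otherwise a seeded
Monte-Carlo with 4000 permutations — because the clump-lead Z universe is
platykurtic and the normal approximation is visibly mis-calibrated at
small k; for larger drugs the closed-form normal is adequate.  The
reported drug z is `−(S−E)/sd` so that positive means protective.  Drugs
need ≥ 2 measured interacting genes; all-undirected drugs are excluded
from the signed test.  ATC level-3 groups need ≥ 5 tested drugs; the
class test is Wilcoxon rank-sum against all other drugs (two-sided on the
signed z, one-sided "greater" on −log10 p for the unsigned statistic),
exact when small and tie-free, midranks with continuity correction
otherwise; a drug in several classes contributes to each unless
restricted.

## Observed differential expression

Plain per-gene Pearson correlation with case status (no covariate
adjustment, matching the upstream description of this analysis, and in
deliberate contrast to the sex-adjusted PTS regressions); p from the
t-transform; BH across genes.  Meta-analysis is on Fisher's z with
variance 1/(n−3) (raw-r IVW behind a flag); single-platform genes pass
through unchanged.  TWAS direction for concordance is the sign of the
mean Z across panels; |mean Z| < 1e−8 is reported as unclassifiable
rather than forced to a side.

## Problem sizes and determinism

The calibration and recovery studies in `twaskit.benchmarks` use 20
replicates of the default study (1000 genes, 4 panels, two platforms of
2000 + 2000) — large enough that Monte-Carlo error is well inside the
tolerances checked, small enough to run interactively.  All randomness
flows from explicit seeds; derived sub-seeds stay below 2³¹.

## Known limitations

Fixed-effect meta-analysis only; no cross-validation or out-of-sample
threshold selection; no imputation of unmeasured genes; the signed drug
statistic is this package's own specified stand-in for directional
gene-set engines, and externally computed drug-level statistics can be
supplied instead, in which case only the ATC layer runs; the liability
conversion assumes the liability-threshold model that the generator
implements, which is what makes parameter recovery a well-posed check.
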