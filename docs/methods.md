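# Methods

## Model

Counts are modelled per sample as one multinomial draw,

```
(N_i1, …, N_id) ~ Multinomial(N_i*, (A_i1/ΣA_ij, …, A_id/ΣA_ij)),
```

so that `N_ij ≈ c_i A_ij` with sampling fraction
`c_i = N_i*/Σ_j A_ij`.  Taxa split into a non-differentially abundant
set J₀, whose absolute abundance is constant across samples, and a
differentially abundant set J₁, whose abundance varies with a latent
per-sample variable.  Identifiability requires |J₀| > d/2: the method
reads the *majority* behavior of the pairwise rank-correlation matrix
as the null, so if most taxa were differential the roles of J₀ and J₁
would swap.  The fitter warns when the estimated non-null proportion
π̂₀ falls at or below 0.5.

## Estimation pipeline and numerical choices

**Rank statistics.** `M_j` is the median over *all* d taxa (the
self-correlation `r_jj = 1` included, matching the statistic's printed
index range; with a majority of non-DA taxa its effect on a median over
hundreds of taxa is negligible).  Ties receive mid-ranks.  Spearman
correlation is undefined for constant vectors, so `filter_taxa` always
removes constant (including all-zero) taxa and the statistics layer
refuses them; the default prevalence threshold is 0 so that, beyond
this necessity, zeros are treated exactly like any other count.  The
full d×d correlation matrix is computed as a rank transform followed by
one matrix product (O(d²n)); above 20 000 taxa it switches to row
blocks to cap memory at the cost of no exactness.

**Null resampling.** The candidate pool is `{j : M_j > γ}`; each of
B = 100 rounds subsamples half of it *without replacement* and
recomputes the per-taxon medians within the subsample.  Sampling with
replacement would duplicate taxa whose mutual correlation is 1 and
inflate the null medians.  Because a Spearman correlation involves only
the two taxa concerned, within-subsample correlations equal the
corresponding entries of the full matrix, so the implementation reads
them off sub-blocks — identical results, no recomputation.  Both B and
the subsample fraction are exposed; the pool must hold at least 10 taxa
and the subsample at least 5.

**π₀ and the threshold.** π̂₀ minimizes
`Σ_{j: M_j>γ} (1 − F̂(M_j) − π₀(1 − F̂₀(M_j)))²`, solved in closed form
as `Σ a_j b_j / Σ b_j²` and clipped to [1e−6, 1]; a grid-search oracle
backs it in the tests.  The threshold scan runs over the sorted unique
M values shifted down by 1e−12 (the selection rule is strict,
`M_j > T`), clamps the estimated misclassification rate to [0, 1], and
stops where the empirical survival `1 − F̂(T)` hits zero; if no grid
point meets the target η the fit fails loudly rather than return an
uncontrolled set.

**Tuning parameters.** η (default 0.05) is the target misclassification
rate of the reference set: smaller η gives a purer but smaller set —
appropriate for bias-sensitive analyses such as differential abundance
testing (the misclassification experiments here use η = 0.01) — while a
larger η gives a bigger, lower-variance denominator better suited to
ordination.  γ (default 0.8) only seeds the null pool.  On shallow or
heavily rarefied data even clearly non-differential taxa can fall below
0.8; `fit_reference_model_robust` then retries with γ = 0.7, 0.6, 0.5
(misclassification control is insensitive to γ over this range, and the
plain fitter's error message recommends exactly this remedy).  The
robust variant is what the null-design pipelines and the benchmark
driver use.

**Normalization.** Size factors are defined only up to one global
constant; they are reported rescaled to geometric mean 1, and
comparisons against planted truth first rescale the estimates so the
means match.  A sample with zero total count over the reference set is
an error — no silent pseudo-count.  GMPR includes the self-pair
(log-ratio 0) in its geometric mean, which makes the factors exactly
proportional on noise-free proportional data; TMM follows the original
published recipe (30% log-ratio trim, 5% abundance trim,
inverse-variance weights, reference sample nearest the median depth)
and is comparator-grade, not bit-compatible with edgeR.  CSS is not
implemented: its scaling percentile comes from an instability heuristic
internal to metagenomeSeq with no self-contained published definition.

**Downstream tests.** The per-taxon t-test is Welch's (unequal
variances), two-sided, run by default on `log(Ñ + pseudo)` with the
pseudo-count set to half the smallest nonzero normalized value (logged
in every result); raw-threshold rejections are the primary output, with
Benjamini–Hochberg rejections reported alongside.  PERMANOVA uses
Anderson's pseudo-F on squared Euclidean distances, the
`(1 + hits)/(1 + B)` Monte-Carlo p-value convention, and exhaustive
enumeration whenever the number of distinct two-group assignments does
not exceed the permutation budget.  **PERMANOVA distances are computed
on the normalized values directly, not on their logs.**  This is a
deliberate choice: with a small pseudo-count, `log(Ñ + pseudo)` turns
the depth-dependent zero pattern of sparse counts into a systematic
location shift between any two groups that differ in depth, and the
test then rejects essentially always on the rarefied null design — for
every normalizer, including ones that demonstrably remove the depth
effect on the value scale.  PCoA, which is descriptive rather than
inferential, log-transforms by default as is customary for ordination
plots; its negative eigenvalues (absent for Euclidean input beyond
round-off) are reported and their axes dropped.

## Synthetic data

The generator is fully parametric: baseline abundances `A_j` are
log-normal (log-mean 0, log-sd 2 — a heavy-tailed abundance
distribution typical of OTU/ASV tables, which also sets the zero
fraction), depths `N_i*` are log-uniform on [2·10³, 5·10⁴], DA taxa get
their abundance multiplied by `signal^x_i` with `x_i` a binary group
label or a Uniform(0,1) draw, and counts are multinomial.  Signal
presets weak/moderate/strong = 1.5/2.5/4.  The default study design is
d = 200 taxa, n = 100 samples, 10% DA taxa, strong signal, balanced
groups.  The null two-group design sets `prop_da = 0`, assigns random
balanced labels, and rarefies group 1 (to 20% of each sample's depth in
the experiments here), making depth a pure confounder.  Everything
derives from one integer seed and the planted truth is returned (and
serializable) for scoring.

What the generator does *not* emulate: taxon–taxon ecological
correlations beyond the shared sampling fraction, overdispersion beyond
multinomial sampling, and the block/batch structure of real studies.
Passing tests therefore show that the estimator does what its model
says under that model — misclassification control, sampling-fraction
recovery, type-I control under a depth confounder — not that any real
dataset satisfies the constant-abundance reference assumption.

One generator-dependent behavior is worth stating plainly: under the
heavy-tailed baseline, rare non-DA taxa are mostly zeros, their `M_j`
are noisy and depressed, and the resampled null (built from the
high-`M` candidate pool) does not cover them.  π̂₀ is then an estimate
of the *well-sampled* non-DA fraction, the threshold lands above the
rare taxa, and the reference set concentrates on abundant taxa.  This
is conservative in the direction that matters — the misclassification
rate stays controlled and the recovered size factors are essentially
exact — at the cost of a smaller denominator than the oracle's.

## Problem sizes

The bundled experiments use 20 replicates of the default design for
misclassification and recovery comparisons, 200 replicates (n = 60
samples) with 99 permutations for the null PERMANOVA study, and 10–25
replicates in the scenario files; these sizes give Monte-Carlo standard
errors small enough for the comparisons made while keeping any single
run in the seconds-to-minutes range.

## Known limitations

* A reference set must exist: data where most taxa shift in absolute
  abundance violate |J₀| > d/2 and the output is untrustworthy (the
  π̂₀ ≤ 0.5 warning is the tell).
* Samples with zero count over the estimated reference set cannot be
  normalized; extremely shallow samples should be dropped upstream.
* Alternative correlation measures (Pearson, Kendall) and analytic null
  models for F₀ are not implemented.
* Baseline normalizers are faithful to their published definitions but
  are not drop-in replacements for the edgeR/DESeq2 implementations.
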