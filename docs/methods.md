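# Methods

This note documents the statistical models behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Study design and preprocessing

The pipeline assumes a paired two-timepoint design (T0 = pre, T1 = post) on an
experimental cohort, with an independent validation cohort sampled at a single
timepoint per subject. Expression matrices are log2 intensities,
features × samples.

**Quantile normalization** forces every sample onto the common distribution
given by the across-sample mean of the order statistics. Ties within a column
receive the mean of the reference values over their rank span — the most
common dialect. With this tie rule the operation is idempotent on tie-free
data; with cross-column tie interactions exact idempotence can fail by small
amounts, which is inherent to any mean-of-tied-ranks scheme and is covered by
a dedicated unit test rather than papered over.

**Detection filter** (applied to miRNAs): a feature is detectable if its
intensity is strictly above `negctrl_mean + 1.5 × negctrl_sd` in at least one
third of the experimental samples. "At least 33%" is implemented as
fraction ≥ 1/3 exactly (2 of 6 passes); the comparison is strict (>) because
the criterion is *above* the background estimate. The filter runs after
normalization by default; a config switch runs it before, since the original
ordering is ambiguous. Background correction (e.g. normexp) is out of scope —
the pipeline consumes background-corrected or simulated intensities.

## Differential expression

Each feature is fitted with the timepoint contrast. The default is the paired
formulation — ordinary least squares on within-subject T1 − T0 differences —
because samples are paired; an unpaired two-group fit is available
(`paired=False`) for designs without subject blocking. Residual variances are
shrunk by empirical Bayes: the observed s² (d residual df) are modelled as
scaled F / inverse-chi-square draws around a prior (d₀, s₀²) estimated by
moment matching on log s² (digamma/trigamma relations, trigamma inverted by
Newton iteration). The moderated t uses the posterior variance
s̃² = (d₀s₀² + d s²)/(d₀ + d) and d₀ + d degrees of freedom. d₀ = 0 recovers
the ordinary t; d₀ = ∞ (flagged when the moment estimate of the log-variance
dispersion is non-positive, or when all variances vanish) pools everything to
s₀². Genes are adjusted by Bonferroni and miRNAs by Benjamini–Hochberg, both
at 0.05 — stricter control for the much larger gene family.

**PCA group test.** Global T0/T1 separation is scored as the between-group
fraction of the total inertia of the sample scores (the full PC rotation is
distance-preserving, so the statistic is computed on column-centered data) and
calibrated by label permutation with the add-one convention:
p = (#{perm ≥ obs} + 1)/(n_perm + 1), so the attainable minimum at 999
permutations is 0.001.

## Target enrichment

Pairwise Pearson correlations between tested miRNAs and DE genes are computed
over all experimental samples, both timepoints pooled (28 columns at the
default design). Pooling is deliberate: the condition-driven covariation that
the anticorrelation filter (r < −0.5, p < 0.05, both strict) targets lives in
the T0→T1 contrast, and per-subject deltas are available as an alternative.
Zero-variance features yield r = 0 flagged degenerate rather than NaN.

Two tests per miRNA with a non-empty targetome (miRNAs without annotated
targets are skipped, not assigned p = 1, so they do not dilute the FDR
correction):

- **Hypergeometric**: upper-tail probability of the observed overlap between
  the targetome and the anticorrelated DE genes, against a population equal to
  the whole expressed transcriptome (not just DE genes).
- **Rank generalization**: one-sided Wilcoxon rank-sum comparing targets' DE
  p-values against all non-target genes. Exact enumeration when the smaller
  group has ≤ 10 members and no ties; otherwise the normal approximation with
  tie and continuity corrections. The two branches agree within 0.01 at the
  switch-over on tie-free data.

Each family is BH-adjusted separately across tested miRNAs (they answer
different questions and are reported separately). A miRNA is *enriched* when
either FDR < 0.10 and at least one of its targets is anticorrelated — rank
significance without anticorrelated targets does not qualify. The full
decision table (counts, both p-values, both FDRs, target lists) is always
emitted so borderline unions/intersections can be audited instead of trusted.

## GGM validation

Conditional (direct) miRNA–gene relationships are modelled by a Gaussian
graphical model whose precision-matrix support is constrained a priori:
miRNA–miRNA entries are structural zeros, miRNA–gene entries are permitted
only for validated targets, gene–gene entries only for known PPI edges. The
estimator maximizes `log det Θ − tr(SΘ) − ρ‖Θ‖₁` over symmetric positive
definite Θ with forbidden entries fixed at exactly zero, by block coordinate
descent (per-column lasso with coordinates restricted to the permitted
support). The diagonal is penalized by default, matching the reference
graphical-lasso convention; this gives the closed form Θᵢᵢ = 1/(Sᵢᵢ + ρ) when
ρ dominates every off-diagonal, and Θ = S⁻¹ at ρ = 0 with a full mask.
Convergence: average absolute change of the working covariance per sweep below
`tol` (default 1e-4; the inner lasso is solved to tol × 1e-3), max 500 sweeps;
non-convergence is flagged on the returned fit, never silent. The covariance
input is the maximum-likelihood (1/n) covariance of column-centered data;
during cross-validation, centering uses training-fold means only.

**Per-miRNA predictability.** GGMs imply a regression of each variable on the
rest with coefficients −Θᵢⱼ/Θⱼⱼ. Each miRNA is predicted under leave-one-out
(chosen because validation cohorts are small, 16 and 31 samples); reported are
the cross-validated MSE and R², where R² is the squared Pearson correlation of
predicted vs observed (the 1 − SSres/SStot variant is behind a flag). A miRNA
with no permitted neighbours falls back to the training-mean predictor with
R² defined as 0. The penalty ρ defaults to 0.03 and can be re-selected by
minimizing the mean leave-one-out MSE over miRNA nodes on a grid, ties broken
toward the sparser (larger) value.

**Permutation null.** The observed (MSE, R²) for a miRNA's candidate gene set
is compared against `n_rep = 500` repetitions in which the same number of
genes is drawn uniformly without replacement from the whole transcriptome and
the identical procedure applied. By default the random sets get their
permitted edges by the same annotation lookup (targetome/PPI applied to the
drawn genes) — literally the same procedure; a topology-preserving mode that
relabels the candidate mask onto the drawn genes is also exposed through a
custom mask builder. p_mse is the plain proportion of repetitions with smaller
MSE (p_r2: larger R²), minimum 0 — deliberately not the add-one convention
used by the PCA permutation test, matching how each procedure is conventionally
reported. Smaller MSE and larger R² count as better; p-values are
BH-adjusted across miRNAs. Each miRNA gets an independent seed stream spawned
from the master seed, so adding or removing a miRNA never perturbs the others.

## Network topology

The first-neighbour subnetwork of a seed gene set keeps the seeds, their
direct neighbours, and only seed-incident edges (neighbour–neighbour edges are
excluded by default; an inclusive flag exists). Topology statistics: degree
distribution P(k) as node counts; per-node clustering 2·triangles/(k(k−1));
mean neighbourhood connectivity; diameter of the largest connected component;
density; Freeman degree centralization Σ(k_max − k_i)/((n−1)(n−2));
heterogeneity as the coefficient of variation of the degrees. The power-law
fit y = βk^a is ordinary least squares on (log₁₀ k, log₁₀ P(k)) with k = 0 and
zero-count entries excluded — a fidelity choice mirroring the common network
tool, not a statistical endorsement of log-log regression for tail estimation.

## Small-RNA discovery

Read filters: length 17–27 nt, mismatches strictly fewer than 2 (i.e. ≤ 1),
at most 6 genome alignments, and no overlap by any base with masked known
ncRNAs. Loci are single-linkage clusters per contig and strand (reads merge
when they overlap or lie within 10 bases — the gap is a package choice);
clusters with fewer than 10 reads are discarded as uninformative. A *stack* is
the set of reads sharing a 5′ start — the biologically anchored end of
Drosha/Dicer products. From the 5′-most stack, the scan repeatedly jumps to
the highest strictly taller stack whose anchor lies within 20 bases downstream
until none remains, yielding the highest local stack (the description of this
rule in the field is ambiguous about which stack "was selected"; this
implementation keeps the taller downstream stack, consistent with the stated
goal). Two precursors are excised per locus — stack + 50 nt upstream / 10 nt
downstream, and the mirror — emulating the mature miRNA sitting on the 3p or
5p arm; flanks are strand-aware, minus-strand sequences reverse-complemented,
clips at contig edges recorded.

The built-in hairpin screen counts the best single-hairpin chain of base pairs
(nested, no multiloop; Watson–Crick plus G·U; minimum loop 3) by an O(L²)
dynamic program, and passes stems of ≥ 16 pairs with loops ≤ 20 nt. It is a
structure-count screen, not a thermodynamic model: thresholds are set so that
perfect planted inverted repeats always pass and homopolymers always fail. An
external folder (e.g. a thermodynamic tool emitting dot-bracket strings) can
be plugged in and replaces the built-in verdict. Candidates whose reads map
solely to the declared mitochondrial contig are flagged mitomiRs and are
reported regardless of the hairpin verdict (with the verdict attached), since
mitochondrial precursors often fail duplex screens yet remain of interest.

## Synthetic data

The generator emulates the study design: 14 paired experimental subjects,
16 T0-only and 31 T1-only validation subjects. Per feature, baseline log2
means are Normal(8, 2) — a common microarray-like regime; negative-control
intensities are summarized as mean 6, SD 0.5 so the detection filter
(threshold 6.75) has a non-trivial operating point. A per-subject random
intercept (SD 0.5) correlates the two samples of a paired subject. DE features
receive an additive log2 shift at T1 (default 1.5, a ~3-fold change — chosen
once as a realistic strong response; the underlying study reports no effect
sizes) with random sign. Planted regulator miRNAs are forced over-expressed at
T1, given baselines comfortably above the detection threshold (so ground truth
is not silently erased by the filter), and transmit
`repression_strength × (miRNA deviation from baseline)` to their target genes,
which are drawn disjointly from the non-DE genes. Noise is independent
Normal(0, noise_sd), default 0.5.

Planted read sets place perfect inverted repeats (default 22 bp arms, 8 nt
loop) in a random genome; reads stack on the mature arm with lengths 20–23 nt;
noise reads are scattered uniformly outside planted loci with a hard guarantee
that no spurious single-linkage cluster reaches 10 reads.

What the generator does **not** emulate: probe-level effects, dye biases,
intensity-dependent variance, correlated gene–gene backgrounds beyond the
subject intercept, bulgy or imperfect hairpins, sequencing error or base
qualities. Passing tests therefore demonstrate correctness of the algorithms
under the planted model, not performance on real arrays or sequencing runs —
in particular, perfect inverted repeats make the hairpin screen's acceptance
analytically forced, and the planted repression is linear where real
miRNA-target coupling is not.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at deliberately modest scale
(hundreds of genes, tens of miRNAs, 100–200 permutation repetitions), which is
ample for the planted effect sizes; all stage seeds are spawned from a single
master seed via independent streams, so identical seeds give byte-identical
outputs and adding a stage never perturbs earlier stages' randomness. The
graphical-lasso sweep kernel is JIT-compiled with numba when available, with
an identical pure-Python fallback.

## Known limitations

- The constrained graphical lasso recovers Θ column-wise; symmetry is enforced
  by averaging at the end (structural zeros are exact by construction).
  With ρ = 0 the input covariance must be non-singular.
- The rank-enrichment test treats the targetome as fixed; selection effects
  from targetome curation are outside the model.
- The hypergeometric test is discrete: its attained size at any nominal α is
  ≤ α and depends on the set sizes, which is why the calibration tests compare
  against the exact attained size rather than α itself.
- Hierarchical clustering heatmaps, GO/pathway enrichment, TF-motif analysis
  and database retrieval (targetomes, PPIs) are out of scope; annotations are
  user-supplied files.
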