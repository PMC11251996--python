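# Methods

`ratioqc` implements a quality-control framework for multi-batch bulk RNA-seq
built around a replicated multi-group reference-material design: several
biological sample groups (canonically four, labeled D5/D6/F7/M8 after the
reference materials derived from a monozygotic-twin family quartet) profiled
in triplicate in every batch. Because the biological differences among such
groups are small and fixed, the design turns each batch into a measurement of
the laboratory's ability to resolve subtle differential expression.

## Signal-to-noise ratio

The central reference-free metric treats the average distance between samples
of *different* groups as signal and the average distance between technical
replicates of the *same* group as noise:

SNR = 10·log₁₀( (Σ_between / N_between) / (Σ_within / N_within) ) [dB]

For the default `ReducedDim_PCA` method, distances are squared differences in
a PCA embedding of the unit-variance-scaled gene × sample matrix, summed over
the first `n_pcs` components (default 2) and weighted by each component's
variance-explained fraction W_p. For a balanced design of m groups with n
replicates the pair counts are N_between = C(m,2)·n² and N_within = m·C(n,2)
(54 and 12 for the 4×3 batch); unbalanced designs use the actual pair counts.
Only the ratio of the weights matters, so any common normalization of W_p
gives the same SNR; the variance-explained *fraction* is used for
interpretability. Features with zero variance are dropped before scaling
(with a logged count) since unit-variance scaling is undefined for them.

Four comparison variants share the signal/noise framing but use plain (not
squared) distances in the original feature space — full Euclidean distance,
the per-feature median absolute difference, and 1 − Pearson correlation — or
Euclidean distance in a seeded 2-D t-SNE embedding (perplexity
min(10, (N−1)/3)). The original-space variants use the matrix as given; the
t-SNE variant is seeded and documented as potentially unstable across library
versions, so exact tests avoid it.

An exactly zero within-group dispersion makes the SNR infinite; results carry
an `infinite` flag and a capped display value of 60 dB so reports stay
serializable. Interpretation anchors: ≈0 dB means group signal is at the
noise level; the conventional acceptability cutoff of 12 dB (mean − s.d. over
the original 21-batch multi-laboratory corpus) ships as a documented default,
not a recomputed value.

### Leave-one-out diagnosis

`snr_leave_one_out` recomputes the SNR with each sample excluded ("SNR11" in
a 12-library batch). If some exclusion raises the SNR by more than 6 dB the
batch's problem is attributed to that replicate (*random failure*, the sample
is named); if the full-batch SNR is below the cutoff and no single exclusion
helps, the failure is *systematic*. Two simultaneous strong outliers defeat
single-exclusion diagnosis by construction — each exclusion still leaves the
other — and such batches surface as systematic failures.

## Ratio-based (relative-scale) expression

Abundances are log-transformed as log₂(FPKM + 0.01); the 0.01 offset keeps
zeros finite (a zero maps to ≈ −6.64). Within each batch, the mean log₂ value
of a designated denominator group's replicates is subtracted per gene from
every sample. Under the additive model

log₂(abundance) = gene baseline + group effect + batch shift + replicate noise

the batch shift is constant within (gene, batch) and cancels exactly; this is
the mechanism that makes cross-batch integration possible at the ratio level.
The cancellation is algebraic; in IEEE-754 arithmetic it is bit-exact only
when every intermediate is exactly representable, which the test suite
demonstrates on dyadic-rational fixtures and verifies to ≤1e-9 on arbitrary
data. Within a single batch the subtraction is a per-gene constant and leaves
all sample–sample distances (hence the SNR) unchanged; the benefits and the
denominator-choice effects appear only when batches are pooled.

Single-replicate denominators are allowed (they matter for cost-constrained
designs) but logged as lower-stability: the denominator's replicate noise is
shared by every ratio in the batch and acts as a residual batch effect of the
noise magnitude.

## Detectability

A gene is detectable in a (group, batch) cell when at least `min_replicates`
(default 2) replicates have at least `min_reads` (default 3) reads.
Cross-batch consensus keeps a gene for a group only if it is detectable in
every batch (or in at least a configurable number). The read threshold is
exposed because the convention is stated both as "≥3" and "more than 3" in
common usage; the inclusive form is the default.

## Differential expression and consensus voting

Per batch, genes are called up/down between two groups when the two-sided
t-test P value is below 0.05 *and* |log₂FC| ≥ 1 (fold change ≥2 or ≤0.5),
with log₂FC = mean(log₂ A) − mean(log₂ B). The default test is the
pooled-variance Student t; Welch and a deliberately simple moderated t
(posterior variance = prior-df-weighted blend of the per-gene pooled variance
with the mean pooled variance, prior df 4) are options. No multiple-testing
correction is applied at the batch level, matching the raw-P gate; BH
correction is available but off by default. Genes with exactly zero variance
in both groups are untestable and reported P = 1 with a degenerate flag.

Reference DEGs are genes concordantly called in more than `deg_min_batches`
batches (default 6, mirroring the "more than six of 13" consensus; the
companion "more than four" convention is reachable through the parameter).
Genes exceeding the threshold in both directions are discordant and labeled
`unassessed` rather than forced into either class.

## Reference-dataset construction

For each ordered group pair, per-batch log₂ ratios are summarized into a
reference log₂ fold change as the arithmetic mean across batches — the log of
the geometric-mean ratio. Inclusion gates: (a) consensus detectability in
both groups in all batches; (b) significance (P < 0.05) in at least
`p_in_batches` batches (default 4, scaled proportionally with ceil and a
floor of 2 when the corpus size differs from 13); (c) when batch protocol
labels exist, no significant protocol difference (kept when P > 0.05 or the
between-protocol fold change stays strictly inside (0.5, 2)).

With exactly-null simulated genes gate (b) retains almost exclusively DEGs;
real corpora retain an order of magnitude more genes because replicate-level
P values are anticonservative. Workflows that need a non-DEG-bearing
reference (MCC scoring) may set `p_in_batches=0` to retain every
consensus-detectable gene.

### Homogeneity

The packaging-unit homogeneity design is deliberately unbalanced: one unit
measured with r replicates (within-unit variance s₂² with r−1 df) and u
units measured once each (between-arm variance v_b with u−1 df; the canonical
design uses r = 9 and u = 16). F = v_b/s₂² is referred two-sidedly to
F(u−1, r−1), P values are BH-adjusted across genes, and a gene passes when
the adjusted P exceeds 0.05. The between-unit variance component is
s₁² = max(v_b − s₂², 0). This follows the described one-vs-many layout rather
than a balanced textbook ISO-style ANOVA. Genes with s₂² = 0 are degenerate
and excluded from the FDR set.

### Stability

Per gene, ordinary least squares of value on storage time (months); the gene
is stable when |b₁| < s(b₁)·t₀.₉₅,ₙ₋₂ (two-sided 95% critical value). A
perfectly constant series (b₁ = s(b₁) = 0) is stable by definition; an exact
deterministic drift (s(b₁) = 0, b₁ ≠ 0) fails. Under a null with Gaussian
noise the pass rate is the confidence level (~95%) by construction.

### Uncertainty budget

Per (gene, pair): u_char is the relative characterization uncertainty,
SEM of the per-batch log₂ ratios divided by |mean|. The between-bottle term
is √((s₁²−s₂²)/n) when s₁² > s₂², else the design's detection limit
√(s₂²/n)·(2/ν)^¼ (ties resolve to the detection-limit branch; the branch is
recorded per gene — no continuity across the branch point is claimed). The
instability term is u_s = t·s(b₁) with t the shelf-life horizon in months
(default: the maximum observed timepoint). Because u_char is relative while
u_bb and u_s arise on the measurement scale, the latter are divided by the
absolute reference value before combination (an all-absolute mode is
available via `relative=False`); the combined and expanded uncertainties are
u_c = √(u_char² + u_bb² + u_s²) and U = k·u_c with k = 2 (~95% confidence).
Records with |reference value| ≤ ε (default 1e-6) cannot carry a relative
uncertainty and are flagged unquantifiable. The per-batch log₂ ratios (not
linear-scale ratios) are the characterized quantity throughout.

## Reference-dependent metrics

Replicate means are taken per group before ratios. RC is the Pearson
correlation between a test dataset's per-gene log₂ ratios and the reference
values over the shared genes (≥3 required); RMSE is the root mean square of
the same differences, on the log₂ scale. MCC scores the test's DEG calls
against reference up/down/non-DEG labels (Eq.-style closed form on the 2×2
counts, defined as 0 with a flag when a marginal is empty). Direction-aware
counting is the default: a reference DEG called with the wrong sign counts as
a false positive *and* a false negative; a direction-agnostic mode exists.
Reference non-DEGs are the reference-ratio genes not labeled DEG.

The total score is √(max(SNR,0)·max(RC,0)) — the geometric mean with
negatives clipped to zero (and flagged), since a geometric mean of negative
quantities is undefined. Cutoffs over a corpus of batches are mean − s.d.
for lower-bound metrics (SNR, RC, MCC) and mean + s.d. for RMSE, with the
sample (n−1) standard deviation given the small batch counts.

### Cross-validation

`cross_validate_reference` repeatedly (default 30 rounds) samples a train
subset of batches, builds a reference from it (count-dependent gates scaled
proportionally, rounded up, floor 2), and scores *all* batches against it.
Split independence is summarized as the per-batch correlation between each
batch's mean metric over rounds where it trained the reference and rounds
where it validated; cutoffs are derived from the validation values.

### Sub-design enumeration

`evaluate_subset_designs` enumerates group subsets of size G with R
replicates. For intra-batch SNR/RC modes it enumerates per-group sample
subsets (e.g. G2R2 on a 4×3 batch gives C(4,2)·C(3,2)² = 54 combinations).
For the denominator-pool mode it enumerates replicate *indices* applied
uniformly across batches — the physically meaningful vial layout — and
computes the pooled ratio-profile SNR; per-batch sample subsets would be
combinatorially explosive and would not correspond to an experimental design.

## Synthetic data generator

`simqc` generates the study conditions the rest of the package is tested
under: 4 groups × 3 replicates per batch; baseline log₂ abundance N(3, 2);
per-group planted effects on a configurable fraction of genes (default 10%)
with |log₂FC| ~ U(1, 3) and random sign against the first group's zero
baseline; replicate noise s.d. 0.2 (log₂); gene-wise additive per-batch
shifts N(0, 1) — the model under which ratio correction is exact — with an
optional multiplicative-on-log contamination (off by default) for robustness
checks; FPKM-like values 2^(log₂ abundance) and Poisson counts at a
configurable depth factor (negative-binomial counts optional, since
detectability only needs small-count behavior). Truth tables (per-pair log₂
fold changes and labels, batch shifts, outlier registry) are emitted, and
regeneration from the same config and seed is bit-identical.

Under these defaults an intra-batch PCA SNR is typically 15–20 dB; a null
configuration (no effects, no batch shifts) centers the SNR at 0 dB. What
the generator does *not* emulate: library-size/composition effects and
FPKM length biases, correlated gene–gene structure, protocol-specific gene
content, anticonservative P-value behavior of real replicates (hence the
note on gate (b) above), and twin-pair relatedness (a correlated-effects
option exists but is off). Passing tests therefore demonstrate correctness
of the algorithms under the additive model, not performance claims about any
real corpus.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on generated data at
deliberately modest sizes — hundreds of genes, 3–13 batches, 50–200 random
repetitions — chosen so every distributional property (null SNR calibration,
type-I error rates, recovery error) has comfortably small Monte-Carlo error
while the whole suite completes in well under a minute of compute.

## Known limitations

- The published cutoffs (SNR 12, RC 0.89, RMSE 0.38, MCC 0.54) and reference
  DEG counts derive from the original real 21-batch corpus; they are shipped
  as documented defaults and are not reproducible from synthetic data.
- The moderated t is a simple shrinkage, not a full empirical-Bayes fit of the
  prior df; for corpus-scale inference a dedicated DE framework is preferable.
- The homogeneity ANOVA assumes Gaussian residuals; heavy-tailed real
  expression noise inflates the nominal type-I rate.
- Ratio profiling corrects genes expressed in the reference material; a gene
  expressed only in study samples keeps its batch effect.
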