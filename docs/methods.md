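# Methods

## The comparison problem

Two species are profiled at the same developmental stage, but only one has
a reference genome. The chicken samples are counted against reference gene
models; the emu samples are counted against gene-level loci of a de-novo
transcriptome assembly. Absolute expression is therefore not comparable
across species: assembly contiguity, annotation transfer losses and
mapping-rate differences act as a gene-wise multiplicative bias on every
emu measurement. The design exploits the fact that such a bias is a
property of the gene-by-species pair, not of the tissue: it multiplies emu
forelimb and emu hindlimb measurements equally and cancels from the
fore/hind ratio. The analysis consequently tests the difference of
within-species ratios — the interaction contrast (EF − EH) − (CF − CH) —
and never a direct cross-species contrast such as EF − CF.

## Annotation transfer

Contig-vs-transcript similarity hits (BLAST tabular format) are processed
with these rules, each chosen to be deterministic:

- hits with e-value ≥ 10⁻⁵ are discarded (strictly-below survives);
- a contig is annotated with the gene of its minimum-e-value hit; ties are
  broken by maximum bitscore, then lexicographically smallest gene ID.
  Multiple transcripts of the same gene are collapsed to the gene before
  tie-breaking — same-gene multiplicity is not ambiguity;
- a locus (cluster of contigs) annotated to exactly one distinct gene gets
  that gene; a locus naming ≥ 2 distinct genes is discarded, because its
  counts cannot be attributed; a locus with no surviving hits is dropped as
  unannotated;
- counts of loci sharing a gene are summed, and the gene-level matrix is
  intersected with the reference species' genes.

Per-sample totals of annotated loci are conserved exactly through
aggregation, and the three locus fates partition the input; both facts are
enforced by tests against a brute-force re-implementation of the rules.

## Expression model

Let c_gi be the count for gene g in sample i and L_i the column total.

- log-CPM: y_gi = log₂((c_gi + 0.5) / (L_i + 1) × 10⁶). The half-count
  offset keeps zeros finite; the +1 on the library keeps the ratio below 1.
- Mean–variance trend: per-gene OLS under the group-means design yields
  residual standard deviations s_g; lowess (span 0.5, 3 robustness
  iterations) of √s_g against average log₂ count gives the trend, which is
  evaluated at each observation's fitted log-count and raised to the −4th
  power to give the precision weight w_gi. Predictions outside the trend's
  range are clamped to its endpoint values, so weights stay positive and
  finite for all-zero genes and saturated genes alike.
- Per-gene weighted least squares with shared design X:
  β̂_g = (XᵀW_gX)⁻¹XᵀW_gy_g, s_g² = weighted RSS / d_g, d_g = n − p.
- Empirical-Bayes moderation: the hyperparameters (d₀, s₀²) of a scaled
  inverse-χ² prior are estimated by moment matching on log s_g² (digamma/
  trigamma inversion; genes with s_g = 0 are excluded from estimation but
  moderated like all others; if the observed spread of log s² does not
  exceed its sampling noise, d₀ = ∞ and all variances collapse to s₀²).
  Then s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) and the moderated
  t = Lᵀβ̂_g / (s̃_g √(Lᵀ(XᵀW_gX)⁻¹L)) is referred to t(d₀ + d_g)
  (normal for infinite d₀). d₀ = 0 recovers the ordinary per-gene t-test —
  a limit used by the test suite to compare against a brute-force classical
  t oracle at 10⁻¹⁰ tolerance.
- Multiple testing: Benjamini–Hochberg step-up, two-sided p-values,
  significance called at adjusted p < 0.05 (strict).
- Candidate ranking: among significant genes, descending
  R_g = |log₂FC_E| − |log₂FC_C| with ties broken by smaller FDR then gene
  ID. R_g rewards genes whose fore/hind asymmetry is specific to the first
  species rather than shared.

The whole chain (transformation, weights, fit, moderation) reproduces the
Bioconductor reference implementation of this methodology to ~10⁻¹¹
relative accuracy on simulated matrices; that agreement is itself a test,
with the reference invoked through Rscript purely as an oracle.

Defaults that matter: log-CPM offset 0.5, library +1, lowess span 0.5,
weight exponent −4, α = 0.05. No between-sample normalization beyond
library size is applied (no TMM), and no low-count prefilter is applied in
the cross-species branch — the annotation intersection is the only gate; a
`min_count` option exists but defaults off.

## Mis-expression branch

The treated-vs-control experiment (3 embryos per arm) is analyzed with an
intercept + treatment + sex design through the same engine, testing the
treatment coefficient. Genes enter only with ≥ 10 counts in ≥ 2 samples.
Sex is inferred from the female-specific W-chromosome marker *HINTW*:
female iff marker CPM strictly exceeds 1.0. Because the marker is
structurally absent in males and highly expressed in females, any small
positive cutoff gives the same calls; 1.0 is the documented, configurable
choice, and the call is invariant to library size. If sex is constant or
exactly confounded with treatment, the sex column is dropped with a warning
instead of leaving the design singular, keeping the treatment test
available.

## Phenotype statistics

Percent reduction is 100 × (1 − treated mean / control mean), rounded
half-up to the integer by default. The two-sample t-test from summary data
uses the pooled-variance Student form (df = n_a + n_b − 2) by default, with
Welch–Satterthwaite as an option; "Student's t-test" in the source
experiments is read as the classic pooled test. Affected proportions are
computed in decimal arithmetic before half-up rounding to one decimal;
a Wilson 95% interval is available. Whether a printed percent reduction was
computed per-embryo or on pooled fields is ambiguous in such experiments;
these functions take whatever group summaries the caller supplies.

## Synthetic data generator

The generator is the package's test bed and emulates exactly the structure
the analysis assumes:

- counts are negative binomial with Var = μ + φμ², φ = 0.1 per gene by
  default (a single-knob dispersion model; real data would show a
  dispersion–mean trend);
- log₂ μ = baseline_g + bias_g·[emu] + tissue_g·[fore] + δ_g·[emu ∧ fore]
  + log₂(size factor). Baselines are N(4, 2²) on the log₂ scale, species
  bias N(0, 1²) applied to both emu tissues (so it cancels in the
  contrast), tissue effects N(0, 0.5²) shared between species, δ_g ≠ 0 only
  for planted interaction genes;
- per-sample library-size targets are uniform on (3.2×10⁷, 4.8×10⁷),
  matching the ~40 million read pairs per limb library of the motivating
  experiments; the size factor scales each sample's expected total to its
  target against a fixed baseline reference total, so planted group-ratio
  effects are realized exactly in expectation;
- assembly simulation splits each gene's counts multinomially across
  1 + Poisson(1) loci (Dirichlet proportions), gives every locus ≥ 1
  contig, and assigns each locus a fate: chimeric with probability 0.05
  (its contigs' best hits name two distinct genes, both below the e-value
  cutoff), unannotatable with probability 0.1 (hits only at/above the
  cutoff, or none), otherwise clean (parent-gene hits with log₁₀ e-value
  uniform on [−50, −6]; spurious extra hits uniform on [−5, 2] so the
  filter provably removes them);
- the mis-expression design plants a 2⁶-fold treatment effect on a
  designated target gene, gives *HINTW* ~100 CPM in females and structural
  zeros in males, and optionally adds sex-affected genes.

Identical configuration and seed give byte-identical outputs; all
randomness flows from `numpy.random.default_rng` seeded once per stage.

What the generator does **not** model: read-level artifacts (it never
touches FASTQ), isoforms, GC/length bias, dispersion trends, correlated
genes, or annotation errors subtler than the chimera/unannotated
dichotomy. Passing recovery tests therefore demonstrate that the inference
machinery is correct under its own assumptions, not that those assumptions
hold in any particular real dataset.

## Numerical and design choices

- Strict inequalities throughout the thresholds (e-value < 10⁻⁵,
  FDR < 0.05, marker CPM > 1.0), matching the stated rules and making
  boundary behavior testable.
- Group-means parameterization (one indicator per group, no intercept)
  with an explicit contrast vector (+1, −1, −1, +1) avoids reference-level
  ambiguity.
- Weighted-LM covariances are computed per gene ((XᵀW_gX)⁻¹ stored
  densely); with p = 4 this is cheap at any realistic gene count.
- Trigamma inversion uses the standard Newton iteration with closed-form
  endpoints for very large/small arguments.
- Degenerate inputs are errors, not silent results: all-zero sample
  columns, rank-deficient designs, all-zero residual variances, single-arm
  designs, missing marker genes.
- Simulation scales in the test suite (≤ 5,000 genes, ≤ 20 seeds per
  property) were chosen so the complete suite runs in well under a minute
  while keeping Monte-Carlo error far below the margins being asserted.

## Known limitations

- The moment-matched prior assumes a single variance population; bimodal
  variance structure (e.g. a subpopulation of near-constant genes) would
  mis-estimate d₀.
- With 2 replicates per group (d_g = 4), individual-gene variance
  estimates are poor and the analysis leans heavily on moderation; this
  mirrors the motivating design rather than a recommendation.
- The ranking statistic R_g is a heuristic for "change dominated by one
  species"; it is not a test statistic and carries no error control beyond
  the FDR gate on membership.
- Annotation transfer trusts best hits; paralog confusion that produces a
  *single* wrong gene per locus is undetectable by the multi-gene rule.
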