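# Methods

This note documents the models implemented in `hybridmhc`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Study system and data model

The package targets amplicon-based expression genotyping of MHC class IIB
(*DAB*) exon 2 in two hybridizing cyprinoid species and their F1 hybrids.
Individuals carry 1–5 expressed alleles drawn from two paralogous gene
lineages (*DAB1*, *DAB3*); allele pools are largely species-specific with
partial trans-species sharing. Each specimen is genotyped from one or
more PCR replicates ("amplicons"), each a tally of distinct read
sequences. Parasite communities are counts of host-specific and
generalist metazoan taxa per individual, strongly structured by season
and host group.

## Allele validation

Artifact filtering is frequency-based and deliberately model-free:

1. **Prefilter.** Variants whose length offset from the reference is not
   a multiple of 3 (frameshift indels) and variants with exactly one read
   in the whole data set are artifacts.
2. **MPAF.** The maximum per-amplicon frequency of a variant is its
   highest read share in any single amplicon. Variants with MPAF ≥ 5%
   (configurable) are accepted.
3. **Artifact explanation.** A low-MPAF variant is, per amplicon that
   contains it, *explainable* if an equal-length variant at Hamming
   distance 1 is strictly more frequent there (PCR/sequencing
   substitution), or if it is an exact single-breakpoint recombinant of
   two strictly more frequent equal-length variants (PCR chimera).
   Frequency ties do not explain: the artifact-generating template must
   be more abundant than its product, and the conservative direction is
   to keep the variant. The default acceptance rule keeps a low-MPAF
   variant when it is unexplainable in at least 50% of the amplicons
   containing it (`acceptance_rule="amplicon_fraction"`); a literal
   per-read variant of the rule (share of the variant's *reads* in
   unexplained amplicons) is available as `"read_share"`.
4. **Coverage.** Amplicons below a minimum read depth (default 100) are
   ignored; specimens with no covered amplicon are reported as "no
   amplification" rather than as zero-allele genotypes.

Chimera detection uses the longest-common-prefix/suffix bound: `v` is a
recombinant of `P1`,`P2` iff `lcp(v,P1) + lcs(v,P2) ≥ L` with a breakpoint
in `[1, L-1]`. This is exactly equivalent to exhaustive breakpoint
enumeration (property-tested) but linear per pair. Breakpoints are
0-based half-open internally and reported 1-based inclusive.

Lineage assignment is by highest sequence identity to user-supplied
*DAB1*/*DAB3* exemplars; ties are reported unresolved rather than forced.

## Diversity statistics

Allele "frequency" is carrier frequency among individuals expressing at
least one validated allele — expression data cannot resolve copy number,
so chromosome frequencies are undefined; a flag switches the denominator
to all specimens. Per-individual allele-count statistics are likewise
computed over expressing individuals only. The sharing partition
(private / pairwise-exclusive shared / shared-by-all counts per group and
lineage) satisfies an exact accounting identity that is fuzz-tested.
Group comparisons use the tie-corrected Kruskal–Wallis H with Dunn's
z-tests as the post hoc (Bonferroni family-wise adjustment by default,
Holm available) — Dunn's test is the standard companion when group sizes
are unequal and the data are heavily tied counts.

## Codon models of positive selection

Substitution follows the GY94 codon process: single-nucleotide changes
only, transition rate scaled by κ, nonsynonymous changes by ω, target
codon frequency π_j multiplying every rate. Codon frequencies default to
F3x4 (per-position nucleotide frequencies), with Fequal, F1x4 and
empirical modes available — the choice measurably shifts PSS counts on
real data, so it is exposed rather than fixed.

The random-site models share κ and a branch-length scale and differ in
the site distribution of ω: M0 (one ratio), M1a (nearly-neutral), M2a
(adds a ω ≥ 1 class), M3 (three free classes), M7 (Beta(p,q) with 10
equal-probability categories), M8 (beta plus a ω_s ≥ 1 spike — 11 site
classes). Beta categories are represented by their category means
computed from the incomplete beta function. Rate matrices are normalized
jointly: branch lengths are expected substitutions per codon under the
*fitted mixture*, and the same convention is used by the simulator, so
parameter-recovery tests are internally consistent.

Likelihoods use Felsenstein pruning with per-node rescaling on
compressed site patterns; the engine is validated against explicit
enumeration of internal-node states on 4-taxon/5-codon instances
(tolerance 1e-8 in log space) and is invariant to re-rooting, as required
for a reversible process. Optimization is bounded quasi-Newton
(L-BFGS-B) on transformed parameters (log for κ/ω/scale, logistic or
stick-breaking for proportions) with multi-start; alternative models are
additionally started from the embedding of their nested null fit
(e.g. M2a from M1a with a vanishing positive class), which enforces
nested lnL dominance in practice. Tests of positive selection are the
LRTs M1a/M2a (df 2), M0/M3 (df 4) and M7/M8 (df 2) against χ²; the null
lies on the boundary of the parameter space, so these are conservative —
confirmed by the 200-replicate null calibration in the test suite.

**BEB.** Per-site posteriors of the positive class integrate the mixture
parameters over a uniform prior grid (10 points per free dimension by
default) rather than fixing them at the MLE: ω0 ~ U(0,1), ω2 and
ω_s ~ U(1,11), (p0,p1) uniform on the simplex for M2a, p0 ~ U(0,1) and
beta shapes p,q ~ U(0,2) for M8. Branch lengths and κ stay at their
MLEs. PSS are sites with posterior P(positive) > 0.95 (or 0.99); the
0.99 list is nested in the 0.95 list by construction.

Trees: a user Newick is preferred; otherwise neighbor joining (scikit-bio)
on JC69-corrected nucleotide distances in per-codon units. Pairwise ML
codon distances would be the purist alternative, but the free
branch-scale parameter in every fit absorbs the calibration difference,
and JC69 keeps tree construction O(n²) and dependency-free; negative NJ
branches are clamped to zero.

## Supertyping

Alleles are embedded as the five z-scale physicochemical descriptors
(hydrophobicity, steric bulk, polarity, two electronic terms) of the
residues at PSS positions, columns standardized (the clustering is
metric-sensitive; standardization is the documented default). K-means is
scanned over k with BIC(k) = n·ln(W/n) + k·d·ln(n) (W = within-cluster
sum of squares); the chosen k is the smallest k at which the BIC decrease
to k+1 falls below 10% of the initial decrease. This explicit formula
and elbow rule are the package's own concretization of "change in BIC" —
the rule expects the within-cluster scatter to shrink gradually with k,
which holds when clusters are balanced and n per cluster is not small
relative to the descriptor dimension. DAPC (PCA retaining 90% variance,
then LDA) yields membership probabilities and modal labels. Consistency
is the fraction of 20 re-seeded K-means runs (labels aligned by Hungarian
matching) agreeing with the reference run; alleles below 0.9 are removed
from downstream analysis. Supertype letters A, B, C… map to clusters by
descending size (ties by centroid lexicographic order) so all outputs are
invariant to K-means label permutations.

## Co-inertia analysis

Both tables are expressed as duality-diagram triplets (table, column
weights, row weights). The binary MHC table gets correspondence analysis
(P/(r cᵀ) − 1 with row/column masses as weights; total inertia = χ²/n);
the parasite table gets a PCA weighted by the CA row masses (centered,
optionally scaled, optional log1p of abundances — untransformed centered
PCA is the default). Co-inertia is the SVD of the weighted
cross-covariance of the two triplets; eigenvalues are squared singular
values and RV = total co-inertia / (‖S_X‖·‖S_Y‖) ∈ [0,1]. The
permutation test permutes rows of the parasite table while the CA row
weights stay attached to the MHC rows — this preserves the CA triplet
under the null — with p = (1 + #{RV* ≥ RV}) / (n_perm + 1), 999
permutations by default. Parasite species at ≤ 2% prevalence in both
parental groups are excluded first; MHC columns are restricted to alleles
carried by ≥ 5 individuals (configurable). Three presets mirror the
standard pairings: alleles × species, alleles × taxon groups,
supertypes × taxon groups, pooled or per host group.

## Parasite-load screens

The GLM series approximates a mixed-model design with deterministic
fixed-effect fits: sampling year enters as a fixed factor instead of a
random intercept, and overdispersion is handled by the negative-binomial
family (dispersion estimated by ML) instead of Poisson observation-level
random effects. This keeps the module self-contained and exactly
reproducible; the cost is slightly anticonservative year inference, which
none of the screened conclusions depend on. Responses: Poisson for
richness, NB for abundance, Bernoulli for prevalence; a taxon at ≤ 30%
prevalence is modeled as prevalence (strict-< mode available, matching
the two readings of the threshold). Presence predictors require > 7
carriers in the analyzed group; rarer predictors make the fits unstable.
Backward stepwise selection on AICc accepts a removal when the reduced
model's AICc is lower or within 2 (simpler model preferred), removes
interactions before their main effects, breaks ties deterministically
(larger likelihood-ratio p first, then lexicographic), and reports a
likelihood-ratio p per removal as a supplementary, non-binding
criterion. A Benjamini–Hochberg-adjusted column is appended per series
as a clearly-labeled supplement, since the screens run many models
without correction.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis expects:

* group sizes 109 / 97 / 88 (bream-like, roach-like, hybrids), 5% PCR
  failure rate, 2 replicates per specimen;
* allele pools 6+24 (bream DAB1+DAB3) and 16+49 (roach), 10% of the
  smaller pool shared trans-specifically per lineage, 2 hybrid-only
  alleles per lineage; alleles are 90 codons (exon-2 scale), ~8 codon
  substitutions from their lineage ancestor, lineages ~30 apart;
* per-individual allele counts in the ranges 1–3 / 1–5 / 1–4 with a
  decreasing count distribution (means ≈ 1.6–1.8); hybrids draw each
  allele from the maternal pool with probability 0.55 (a slight maternal
  bias), maternal line recorded;
* amplicons: depth 300, Dirichlet(1) amplification skew across a
  specimen's alleles, 1% per-read 1-bp substitution rate, 2% per-read
  single-breakpoint chimera rate (breakpoint uniform over internal
  positions, both parents from the same amplicon). No base-quality or
  primer/adapter modeling. Read depth and error rates are not published
  for the system, so they are config-exposed; the defaults produce the
  low-MPAF stress regime the 5% rule is designed for;
* parasites: ten taxa spanning host-specific monogeneans and generalist
  crustaceans/digeneans/cestodes, negative-binomial counts (dispersion
  0.5) with log-link effects — spring multipliers (3× for ectoparasites),
  host-specific means (zero in the wrong host, 30% carried over to
  hybrids), and optional planted allele → taxon log effects.

All randomness flows from one top-level seed through named substreams
(`SeedSequence([seed, crc32(stage)])`), so each stage is independently
reproducible and full runs are byte-identical — this is asserted in the
acceptance suite.

What the generator does *not* emulate: linkage between lineages within
haplotypes, copy-number variation, shared-ancestry correlation between
allele sequence similarity and carrier frequency, read-quality profiles,
and spatial/temporal autocorrelation in parasite exposure. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical structure, not robustness to every property of real MiSeq
amplicon data.

## Numerical choices and degenerate inputs

* Reversible rate matrices are exponentiated via symmetric
  eigendecomposition (exact to machine precision, stable for any branch
  length); transition rows are clipped/renormalized against negative
  round-off.
* Site patterns are compressed before likelihood evaluation; per-site
  outputs are expanded back through the pattern index.
* Optimizer convergence |Δℓ| tolerance 1e-6 (gtol), 500 iterations,
  default 3 starts (1 deterministic + perturbations); non-convergence is
  flagged on the fit, never silent.
* Sequences are compared after uppercasing and U→T normalization;
  variants containing ambiguity codes are flagged and excluded from
  validation rather than guessed.
* Empty amplicons, zero-grand-total CA tables, constant matrices in the
  RV test, empty groups in Kruskal–Wallis, and zero-variance responses
  in the GLM series all raise or skip with explicit reports.
* Logistic separation in Bernoulli fits (|coef| > 15) is flagged and
  refit with a small L2 penalty; the penalized log-likelihood is then
  used for AICc.

## Known limitations

* The site-model optimizer can in principle find local optima for M8 on
  small alignments; the nested-embedding start makes the LRT conservative
  rather than anticonservative in that case.
* BEB grids are O(G⁴) in the grid density for M8; the default G=10 is
  the conventional density, and tests use G=6–8 for speed.
* The stepwise screen inherits the usual caveats of single-path model
  selection; the reported per-removal p-values are supplementary, not
  simultaneous inference.
* Exact reproduction of published PSS counts from deposited alleles
  depends on unstated tree and codon-frequency choices; the selection
  module exposes both so the sensitivity can be mapped.
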