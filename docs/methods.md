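# Methods

`beefgwas` implements a complete association-analysis chain for
quantitative meat-quality traits in an admixed beef-cattle population,
together with a synthetic data generator that reproduces the statistical
structure the chain assumes.  This note records the models, the defaults
and the design decisions; everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Mixed-model association scan

For one trait the model is

    y = X b + u + e,    u ~ N(0, σ²_a G),    e ~ N(0, σ²_e I)

with `G` the VanRaden method-1 genomic relationship matrix built from
centred dosages, `G = W W' / (2 Σ p_j (1 − p_j))`, `w_ij = x_ij − 2 p_j`.
Missing dosages are mean-imputed per variant before any matrix algebra;
monomorphic variants are a hard error (quality control must run first).
Fixed effects default to an intercept plus year-of-birth dummies.  Breed
composition is deliberately **not** a fixed covariate by default: the
admixture confounding is left to the GRM, which is how the analysis the
package reproduces specified its model; `extra_covariate_columns` lets a
user add structure covariates if wanted.

Variance components are estimated by REML under the null (no-SNP) model.
The ratio λ = σ²_a/σ²_e is profiled on a single spectral decomposition of
`G` (eigenvalues clipped at zero; matrices whose smallest eigenvalue is
below −0.01·λ_max are rejected as indefinite).  λ is optimized on the
log₁₀ scale over [−5, 5] by a 61-point grid followed by bounded scalar
minimization; an optimum pinned at either end is flagged `at_boundary`
(the low end is reported as σ²_a = 0) rather than treated as an error.
The estimates match a brute-force dense-matrix likelihood grid to within
one grid step (tested), and with an informative (structured) `G` the null
estimate concentrates at the zero boundary.

Each marker is then tested by generalized least squares with
`σ²_a G + σ²_e I` held fixed at the null estimates — the standard
one-variance-fit (EMMAX-style) approximation, which reduces exactly to
ordinary least squares when σ²_a = 0 (tested against closed-form OLS).
The test is a 1-df two-sided Wald χ², with the residual variance
re-estimated per marker model.  Exact per-marker REML is available behind
`per_snp_reml=True`; it is O(n³) per SNP and intended for candidate
regions only.  A SNP collinear with the covariates is reported with a
missing p-value and a reason, never silently dropped.

The conditional scan appends the conditioning SNP's (mean-imputed) dosage
to the fixed effects and excludes it from the output — the device used to
show that one index SNP explains a whole associated region.  The joint
model fits a gene's pruned SNPs simultaneously and applies backward
elimination: while any joint Wald p exceeds α (default 0.05), the least
significant SNP is removed, ties broken by larger p then larger input
index so the trace is deterministic.

## Phenotype preprocessing

WBSF is log-transformed (values must be positive).  Marbling and
connective tissue are normalized with a Johnson SU transform fitted by
the Slifker–Shapiro quantile rule (quantiles at ±0.524 and ±1.572
standard-normal points); when the quantile spreads fall outside the SU
region or the fitted transform would not be strictly increasing, the
deterministic rank-based inverse-normal transform (Blom offsets, average
ranks) is used instead.  Both are strictly monotone, so ranks — and hence
any rank statistic — are preserved; the original tool's exact Johnson
variant is closed-source and not reproducible, and either monotone
normalizer serves the same purpose.  Other traits pass through unchanged.
Distribution fitting requires ≥ 30 non-missing values.

## Significance thresholds

The effective number of independent tests M_eff is computed simpleM-style:
each chromosome is processed in windows of at most 133 consecutive SNPs
(the published block-processing default; configurable), the Pearson
correlation matrix of mean-imputed dosages — the composite-LD correlation
for unphased data — is eigendecomposed, negative eigenvalues are clipped
at zero, and the window's M_eff is the smallest k whose leading-k
eigenvalue share reaches C = 0.995.  The genome-wide threshold is
0.05 / ΣM_eff.  With C = 1 the window M_eff equals the numerical rank of
the correlation matrix, and M_eff is invariant to allele-coding flips
(both tested).

Hits are tiered per trait: genome-wide (p ≤ 0.05/M_eff), a secondary tier
(p ≤ 1×10⁻⁴) reported only for traits with no genome-wide hit, and "raw"
(p ≤ 0.05, the enrichment inclusion rule; all comparisons inclusive).  On
very small panels 0.05/M_eff can exceed the secondary cutoff; the two
tiers are then collapsed rather than mis-ordered.  Benjamini–Hochberg
adjustment takes an `m_override` so the step-up denominator can be M_eff
(GWA) or the number of tested pathways (enrichment); it is checked
against an independent reference implementation.

## SNP→gene assignment and LD pruning

A SNP belongs to a gene when it lies inside the gene or within 3 kb of
either end (inclusive boundaries, strand-agnostic, multi-assignment
allowed).  Within a gene and trait, the raw associated SNPs (p ≤ 0.05)
are pruned greedily in order of ascending p (ties by position, then ID):
a SNP is kept iff its squared Pearson dosage correlation with every kept
SNP is ≤ 0.3.  The source description of this step mixes "correlation
based on p-value" with "r² > ±0.3"; genotype LD is the only quantity for
which "uncorrelated SNPs within a gene" is meaningful and r² cannot be
negative, so r² is defined here as squared dosage correlation and the
"±" read as a typo.  Every dropped SNP is explained by a kept SNP of
smaller-or-equal p (tested), and when all raw SNPs are mutually
correlated the gene keeps exactly its best SNP.

## Tissue-restricted enrichment

The background is the set of genes expressed in the target tissue
(skeletal muscle in the motivating application, 10,919 genes at full
scale); genes outside it never enter a gene list, and the same set is the
enrichment population.  A trait's gene list is a multiset — one entry per
retained uncorrelated SNP — so a gene with several independent signals
counts several times.  For each GO term annotated to ≥ 2 background genes
(singletons only inflate the adjustment denominator), a hypergeometric
test compares k (list entries annotated to the term, with multiplicity)
against K (background genes with the term), n (list size with
multiplicity) and N (background size).  Multiplicity enters k and n only:
the background and GO universe are sets.  Because multiplicity can push k
past the term's gene count, k is capped at min(n, K) to stay on the
hypergeometric support.  Both tails are always computed —
over-representation P(X ≥ k) is the default reading, but the
published count patterns for this kind of analysis are sometimes only
consistent with depletion, so P(X ≤ k) is reported alongside.  A
`unique` flag collapses multiplicity entirely.  BH adjustment runs per
trait over exactly the tested terms.

Because the hypergeometric statistic is discrete, its null p-values are
super-uniform rather than exactly uniform; the calibration test therefore
compares the permutation-null rejection rate against the *exact* discrete
null probability P(p ≤ α) enumerated from the pmf, instead of applying a
continuous-uniformity (KS) check that discreteness would fail by
construction.

## Gene–trait network

The network is the genes × traits matrix w[g, t] = number of kept
uncorrelated SNPs.  Connectivity is the row/column sum of w (the weights
are SNP counts, so summing them is the natural degree; a trait-count
alternative is exposed because the original description never defines
"connectivity" formally).  Ranking ties break by trait spread, then gene
ID.  Trait–trait edges carry pairwise-complete Pearson correlations of
the transformed phenotypes — pairwise-complete because sensory traits are
scored on fewer animals than carcass traits.  The top-5 genes (default
m = 5, mirroring the candidate-gene follow-up) go to the joint model for
every trait where they hold ≥ 2 kept SNPs; the m-th/(m+1)-th connectivity
ratio is reported as a descriptive gap, not a test.

## Gabriel LD blocks

Two-locus haplotype frequencies come from EM over the double-heterozygote
phase ambiguity (all other genotype classes contribute fixed haplotype
counts); the EM log-likelihood is non-decreasing on every fixture and the
fixed point matches a fine likelihood grid (both tested).  The |D′|
confidence interval is likelihood-based: with allele frequencies fixed at
the EM estimates, the multinomial genotype likelihood is evaluated on a
101-point grid of |D′| signed by the point estimate, normalized, and the
(1−conf)/2 and 1−(1−conf)/2 mass points taken as bounds (conf = 0.90).
A pair is "strong LD" when ci_low ≥ 0.70 and ci_high ≥ 0.98 — the
"minimum 98% confidence" strong-LD rule with the standard lower bound —
and "recombinant" when ci_high < 0.90.  Candidate blocks need a strong
outermost pair and ≥ 95% strong among informative pairs; overlapping
candidates are resolved longest-first (bp, then SNP count), matching the
reference software's behaviour.  All four cut-offs are configurable.

## Synthetic data generator

The generator's defaults are the study conditions: 672 steers (495 with
sensory scores), six breed-composition groups with expected Angus
fractions 0.9/0.72/0.625/0.5/0.3/0.1, a 3,000-SNP panel (a ~250k bovine
chip scaled down; SNPs every 10 kb), and seven traits at heritabilities
0.50 (marbling), 0.47 (tenderness), 0.17 (WBSF) with a WBSF–tenderness
genetic correlation of −0.97.  Heritabilities for the remaining traits
(cooking loss 0.30, juiciness 0.25, connective tissue 0.30, flavor 0.15)
are not published for this population and are set to values typical for
carcass/sensory traits in beef cattle.

**Genotypes.**  Chromosomes are tiled with LD blocks (mean 10 SNPs,
Poisson-varied lengths; an exact-length switch exists for block-boundary
tests).  Within a block, each haplotype is drawn from a founder pool of
~1/r² haplotypes per ancestral population (default pool 2, giving strong
within-block LD); between blocks draws are independent, so recombination
happens only at block boundaries — a deliberately stylized LD model chosen
over a coalescent because block-recovery tests need exact generating
boundaries.  Population allele frequencies diverge by a Balding–Nichols
model (Fst = 0.1) around ancestral frequencies ~ U(0.1, 0.9); each
haplotype's population-of-origin is drawn per block from the sample's
breed-group admixture proportion, reproducing the ancestry confounding
the GRM must absorb.  Columns monomorphic across all reachable founder
pools are redrawn (and finally allele-flipped) so every emitted SNP
segregates; sample-level MAF filtering is still the QC stage's job.

**Phenotypes.**  On a unit-variance latent scale per trait:
year effect (SD 0.1) + planted QTL effects + polygenic value + residual.
Polygenic values across traits are drawn from N(0, Σ ⊗ G*) where G* is
the realized GRM normalized to unit mean diagonal and Σ carries the
polygenic variances (h² minus the trait's planted-QTL fraction) and the
genetic correlation matrix — so cross-trait breeding-value correlations
are exact in distribution and REML sees exactly the model it fits.  QTL
effects are placed on the most polymorphic SNP of each of the gene's
blocks (one causal SNP per block, keeping causal SNPs mutually
uncorrelated) with equal variance shares and random signs.  Traits are
then emitted the way they are measured:

* WBSF: six core peak loads, log-normal around 4.30 kg (CV 0.267), with
  per-core noise worth 0.1 latent variance; the trait is the core mean.
* Sensory traits: integer 8-point scores from a 9-member panel (panelist
  disagreement SD 0.7 score units), clipped to 1–8 and averaged; only the
  495 sensory animals get values.
* Cooking loss: percentage from simulated thaw/cooked weights.
* Marbling: integer 100–999 score via a mildly right-skewed sinh map
  (so the Johnson SU normalization has real work to do).

Rounding, clipping and panel averaging add ~1% extra phenotypic variance,
which is why realized heritabilities sit marginally below the configured
values; the tests bound this at ±0.05 and the REML-recovery acceptance
band is ±0.07.

**Annotation.**  100 genes tile the blocks (QTL genes span one block per
causal SNP; one intergenic block between genes).  A 150-term GO
vocabulary is assigned at ~3 random terms per gene; one planted term
annotates all causal genes plus 12 random others — broad enough that the
causal genes' summed multiplicity is not truncated by the term's gene
count, which is what makes the planted term detectable against narrow
noise terms that happen to contain one causal gene.  The background list
holds every causal gene plus 90% of the rest.

**Default planted QTLs.**  Three genes, each with three causal SNPs
affecting two traits (gene → cooking loss + one of marbling, juiciness,
flavor; 6% of phenotypic variance per gene-trait, 4.5% for flavor to fit
its h²).  No QTL touches WBSF or tenderness, so their breeding-value
correlation is governed purely by the polygenic −0.97.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic bovine demography and recombination
maps, genotyping error, family pedigree structure (the LD panel's 196
families are emulated only as a sample size), gene-length and LD-aware
enrichment nulls, GO-graph propagation, selection and heterosis.  The
generator is a model-faithfulness instrument, not a population simulator.

## Problem sizes used by tests and the acceptance script

Parameter-recovery runs use the full study scale: 672 samples × 3,000
SNPs with 20 replicates for heritability recovery (estimates within
±0.07 of 0.50 and 0.17), 10 replicates for the breeding-value correlation
(±0.02 of −0.97) and the end-to-end planted-signal recovery, 5 × 2,000
SNPs for null calibration (raw rate 0.05 ± 0.01), and 569 samples × 12
SNPs × 10 replicates for Gabriel-block recovery.  Unit tests run on
panels of tens-to-hundreds of samples.

## Known limitations

* Single-trait REML only; the genetic-correlation machinery lives in the
  generator, not the estimator.
* The EMMAX approximation slightly mis-calibrates when a single SNP has a
  large effect on the variance scale (standard trade-off; exact per-SNP
  REML is available behind a flag).
* Johnson normalization falls back to inverse-normal for heavily tied or
  non-SU-shaped samples; the two transforms differ in tails.
* The Gabriel implementation classifies pairs from unphased EM estimates,
  as the reference software does for unrelated samples; family-based
  phasing is out of scope.
* `enrich_all` refuses multiplicity-inflated lists larger than the
  background (the hypergeometric draw would be ill-defined).
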