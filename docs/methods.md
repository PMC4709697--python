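# Methods

`radgs` evaluates how well reduced-representation (type IIB RAD) marker
panels support genomic selection. It simulates a genome and its
restriction-tag marker panels, breeds populations forward in time,
generates phenotypes at controlled heritabilities, fits seven
genomic-prediction models, and measures cross-validated accuracy of
estimated breeding values. This note records the models, the parameter
choices that matter, and the limits of what the simulations show.

## The shared linear model

All estimators address

    y = mu + Z w + X g + e

with `y` phenotypes, `X` the marker dosage matrix (0/1/2 copies of the
alternate allele for genotypes AA/AB/BB), `w` optional family fixed
effects (design matrix `Z`), `g` marker effects, and `e` Gaussian error.
Breeding values are predicted as GEBV = X g-hat for marker-effect
methods, or as the BLUP of the genetic value projected through a
relationship matrix for the kinship methods.

* **Pedigree BLUP** — mixed-model BLUP with the numerator relationship
  matrix A (tabular method). Variance components by REML.
* **G-BLUP** — the same solver with the marker-derived relationship
  G = (X − 2p)(X − 2p)'/k, k = Σ_j 2 p_j (1 − p_j).
* **RR-BLUP** — ridge regression of y on all markers with
  λ = σ_e²/(σ_g²/k). With the shared k this is algebraically the dual of
  G-BLUP: training GEBVs agree to machine precision (a core test).
  The printed per-marker form of k in the source material is ambiguous;
  the summed form is used because it restores this duality.
* **BayesA** — Gibbs sampler; g_j ~ N(0, σ_gj²) with locus-specific
  variances σ_gj² ~ scaled-inv-χ²(ν, S).
* **BayesB** — as BayesA with a point mass at zero: g_j = 0 with prior
  probability π (spike-and-slab, indicators sampled from the integrated
  likelihood ratio). π = 0 reproduces BayesA.
* **Bayesian LASSO** — double-exponential prior via the normal scale
  mixture g_j | τ_j² ~ N(0, τ_j² σ_e²), τ_j² ~ Exp(λ²/2); λ² fixed or
  given a diffuse Gamma hyperprior (default).
* **LASSO** — ℓ1-penalized least squares by cyclic coordinate descent,
  penalty chosen by cross-validation inside the training split.

REML for a single random effect is computed by eigendecomposition of the
relationship matrix and 1-D profile-likelihood maximization over the
variance ratio (bounded search on log λ ∈ [−12, 12]; boundary estimates
are flagged, not raised). Standard errors come from the curvature of the
profiled restricted likelihood via the delta method.

### MCMC settings

Package defaults: 1,500 iterations, 300 burn-in, thin 5; BayesA/B prior
ν = 4.2 with scale S set so the prior total marker variance matches half
of var(y); BayesB π = 0.95; residual prior scaled-inv-χ²(4, var(y)/2).
Samplers are seeded and bit-reproducible; a split-chain R-hat for σ_e²
is reported in `diagnostics_`. The scenario runners and the acceptance
script use 600 iterations / 150 burn-in: the simulated signals are
strong, results are averaged over five folds and ≥10 replicates, and the
split-chain diagnostic stays ≈1 at this length.

### Family effects

Family is fitted as a fixed effect only where the data-generating
process contains a family environmental component (the empirical-style
dataset). Simulated phenotypes have no family environmental term, so the
true w is zero there; fitting spurious family effects would absorb
between-family genetic signal into fixed effects and understate
accuracy. Predicted GEBVs never include the family effect — they are
breeding values; `predict_phenotype` adds μ and w on request.

## In-silico marker panels

BsaXI excises a 29-base tag, written 5'→3' as N10-AC-N5-CTCC-N8; both
strands are scanned (the reverse-complement motif on the forward strand
is GGAG-N5-GT), and a position can match at most one strand. RTR
(reduced tag representation) libraries with 5'-NNA-3' selective adaptor
overhangs retain tags whose own-strand sequence starts with A and ends
with T — 1/16 of tags under uniform base composition, ≈1/10 at the
AT-rich composition used here (GC 0.35), matching the fraction reported
for real molluscan genomes. Panels:

* **HD** — evenly spaced SNPs at a target density (250/Mb);
* **MD** — every SNP inside a BsaXI tag;
* **LD** — every SNP inside an RTR tag.

At GC 0.35 and a 2% SNP rate the emergent densities are ≈200 tag
sites/Mb, ≈70 tag SNPs/Mb (≈58/Mb still segregating after burn-in) and
≈6 segregating RTR SNPs/Mb — close to the 250, 63 and 5 per Mb of the
motivating 2b-RAD assay. Coordinates are 0-based half-open; a SNP at p
belongs to tag [s, s+29) iff s ≤ p < s+29.

## Breeding simulation

The burn-in is a neutral Fisher-Wright model: discrete generations,
census 500, random union of gametes, 1,000 generations, symmetric
bi-allelic mutation at 1e-5 per copy per generation, recombination with
Poisson crossover counts under the Haldane map function at 1 cM/Mb,
independent chromosome assortment. Only loci that can enter a panel (or
are QTLs) are tracked.

**Founder initialization.** SNPs are injected into a single diploidized
reference, so the founding population carries exactly two ancestral
haplotypes: every SNP starts at frequency 1/2 with complete
(random-sign) founder LD, which recombination and drift then erode over
the 1,000 generations. This "diploid" mode is what the scenario builders
use; it reproduces the strong local LD that gives low-density panels
their high accuracy. An independent-loci linkage-equilibrium mode
(frequencies uniform on (0.05, 0.95)) is also available and is the
generic default of `burnin_fisher_wright`; under it, LD-panel accuracy
saturates around 0.84 instead of ≈0.9.

Mating designs (full-sib batches with recorded pedigree):

* population-based: 100 sires × 100 dams from the burn-in population,
  20 offspring per pair (2,000 per generation), repeated for a second
  generation;
* family-based: 20 families × 50 offspring from 10 sires and 10 dams
  (each parent serves in two matings, distinct pairs enforced), and a
  5-family × 50 variant for the dominance scenario.

QTLs (5,000 per 970 Mb, scaled per Mb) get additive effects a_j ~
N(0, 1); TBV_i = Σ_j x_ij a_j. Dominance, when enabled, adds d_j for
heterozygotes with d_j ~ N(0, 1) rescaled so the realized dominance
share of phenotypic variance hits its target (default reading: additive
h² = 0.3 and dominance share 0.3 of phenotypic variance, residual 0.4; a
"genetic-denominator" reading is selectable). The error variance is
calibrated from the realized additive variance of the phenotyped sample:
σ_e² = V_A (1 − h² − s)/h².

## Desk-scale study conditions

The full-size study (a ~970 Mb genome, 250k/61k/5k panels) is scaled to
a 50 Mb genome in 5 chromosomes with per-Mb marker and QTL densities
preserved. Rationale and caveats:

* Accuracy at these designs depends on markers per Morgan, QTLs per
  Morgan (both preserved) and on the *absolute* marker count through the
  precision of marker-estimated relationships; below ~150 panel markers
  that noise dominates, so the genome is kept at the top of the
  desk-scale band (LD ≈ 290 segregating markers at 50 Mb).
* The family designs use a fixed 2,364-marker panel drawn from
  segregating BsaXI-tag SNPs. A 50 Mb genome yields only ≈300 RTR-tag
  SNPs, so the RTR class is relaxed to all-tag SNPs for this panel;
  marker count, family structure and sample sizes are kept at study
  scale.
* Replicates: the acceptance script runs 10 independent replicates of
  every scenario (one 5-fold CV partition each); the test suite runs 3-4.
  These sizes keep a full reproduction within desk-scale runtimes.

## The empirical-style synthetic dataset

`synth_empirical_dataset` emulates the *structure* of a real 5-family
aquaculture dataset: 349 individuals (70/70/70/70/69), 2,364 segregating
(MAF > 5%) markers, three correlated growth traits (SH, SL, SW; genetic
correlation 0.6) with variance components matching a REML analysis of
the real material (σ_a² 14.58/16.30/2.66, h² 0.48/0.48/0.36), 16%
missing genotypes at random (mean call rate 84%). Two families descend
from one sub-population and three from another, diverged for 100
generations, so genotype PCA separates the groups; family phenotype
differences are mostly genetic with a small common-environment term (5%
of σ_P per family).

What it does **not** emulate: genotyping error and allele-dropout,
depth-dependent missingness (missingness here is MCAR), multi-allelic
QTLs, selection history, linkage maps estimated from the real genome.
Passing tests on this generator show the *pipeline* behaves correctly on
data with realistic structure; they do not validate accuracy claims on
real scallop data.

## Numerical choices

* Genotypes are dense uint8 haplotypes (n × 2 × L); meiosis draws
  Poisson crossover counts and copies parental segments in a compiled
  kernel. Under no interference the parental-origin process along the
  map is Markov, so switch points are uniform on the concatenated map.
* Mutation hits are sampled with replacement (a duplicate hit flips a
  site twice); at realistic rates the bias is negligible.
* G is symmetrized and its eigenvalues clipped at zero; matrices with
  eigenvalues below −1e−6·max|K| are rejected with a hint to blend with
  the identity (`GBLUP(blend=...)` — off by default because blending
  breaks the exact RR-BLUP duality).
* The LASSO penalty path is 50 log-spaced values from λ_max down to
  1e−3 λ_max with warm starts; ties in CV error resolve to the larger
  penalty index order (argmin of the summed fold error).
* Constant EBV vectors in a CV repeat are recorded as missing with a
  warning rather than raising.
* Fixed-effect design matrices are rank-reduced by QR before REML, so
  redundant family dummies are harmless.

## Known limitations

* The forward simulator is neutral: no selection during burn-in, no
  overlapping generations, no sex chromosomes.
* Estimators are additive-only (the dominance scenario is fitted with
  additive models on purpose, to quantify the resulting accuracy loss).
* The Bayesian samplers use single chains; the split-chain R-hat on
  σ_e² is a coarse convergence check, adequate for the strong-signal
  simulated scenarios but worth increasing chain length for weak-signal
  real data.
* Pedigree BLUP requires complete, acyclic pedigrees with parents
  listed before offspring; unknown parents are founders.
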