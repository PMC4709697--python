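# radgs

Genomic selection with reduced-representation marker panels: simulation,
whole-genome regression models, and accuracy evaluation.

Aquaculture breeders increasingly genotype with restriction-site
associated sequencing. Type IIB enzymes such as BsaXI excise a uniform
29-base tag (5'-N10-AC-N5-CTCC-N8-3') around every recognition site, and
selective "reduced tag representation" (RTR) adaptors with 5'-NNA-3'
overhangs subsample those tags roughly tenfold. The practical question
is whether the marker densities these assays deliver — tens of SNPs per
Mb for a standard library, a handful per Mb for an RTR library — are
dense enough to estimate genomic breeding values accurately, and which
statistical model to use. `radgs` answers that by simulation: it builds
a genome and its tag-derived marker panels in silico, breeds populations
forward in time under a neutral Fisher-Wright model, generates
phenotypes at controlled heritability, and scores seven
genomic-prediction models by cross-validated accuracy,
r(GEBV, true breeding value).

All models address the linear model **y = μ + Zw + Xg + e** with X the
0/1/2 marker dosage matrix: pedigree BLUP (numerator relationship matrix
A), G-BLUP (genomic relationship G = (X−2p)(X−2p)′/k with
k = Σ 2pⱼ(1−pⱼ)), RR-BLUP (ridge with λ = σ²ₑ/(σ²_g/k) — the exact dual
of G-BLUP), BayesA (locus-specific scaled-inv-χ² effect variances),
BayesB (spike-and-slab with prior exclusion probability π), the Bayesian
LASSO (double-exponential prior via Gibbs sampling) and the plain LASSO
(coordinate descent, CV-chosen penalty). The Gibbs samplers and
coordinate descent are implemented here (numba-compiled) and tested
against closed-form, quadrature and enumeration oracles. Estimators
follow the scikit-learn protocol (`fit`/`predict`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
model selection.

See `docs/methods.md` for the models, priors, simulation parameters and
their rationale.

## Worked example

Simulate a desk-scale breeding population (50 Mb genome, 2% SNPs,
BsaXI/RTR tag panels, 1,000 generations of burn-in, then 100 sires ×
100 dams × 20 offspring), phenotype it at h² = 0.5, and compare G-BLUP
with BayesA on the low-density RTR panel by 5-fold cross-validation:

```python
import radgs
from radgs.experiments import simulate_population_scenario, make_models
from radgs.popsim import simulate_phenotypes
from radgs.evaluation import cross_validate, CVScheme

data = simulate_population_scenario(seed=11)
print({name: len(cols) for name, cols in data.panels.items()})

phen = simulate_phenotypes(data.tbv_g1, h2=0.5, seed=42)
models = make_models(["G-BLUP", "BayesA"], niter=600, burnin=150, seed=1)
res = cross_validate(data.genotypes("LD"), phen.phenotype, models,
                     CVScheme(n_folds=5, n_repeats=1, seed=2),
                     tbv=data.tbv_g1)
print(res[["method", "accuracy", "slope"]])
```

Output:

```
{'MD': 2922, 'LD': 292}
   method  accuracy     slope
0  G-BLUP  0.876988  0.995965
1  BayesA  0.874917  1.014448
```

The 50 Mb genome carries 2,922 segregating tag SNPs (≈58/Mb) of which
292 fall in RTR tags (≈6/Mb). Even the 292-marker RTR panel predicts
breeding values with accuracy ≈0.88 at h² = 0.5 — within a few points of
the all-tag panel — because 1,000 generations of drift in a closed
population leave strong local linkage disequilibrium, and full-sib
family structure does the rest. Regression slopes of phenotype on GEBV
near 1 indicate unbiased prediction.

The same machinery is scriptable from the shell:

```bash
radgs simulate-genome --chromosomes 5 --length 10000000 --seed 1 --out genome
radgs build-panels --fasta genome.fasta --snps genome.snps.tsv --hd-size 2500 --out panels
radgs synth-empirical --seed 7 --out scallops     # 349 x 2,364 five-family dataset
radgs cross-validate --geno scallops.vcf --pheno scallops.pheno.tsv \
      --trait SH --methods G-BLUP,BayesA,BayesB --h2 0.48 --out cv.tsv
radgs run-experiment --config config.yaml --out-dir results/
```

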