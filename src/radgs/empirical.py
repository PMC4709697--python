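"""Synthetic stand-in for a multi-family aquaculture genotyping study.

Generates a 5-family, 349-individual dataset genotyped at 2,364
reduced-representation SNPs with three correlated growth traits (shell
length SL, shell width SW, shell height SH, in mm) and missing genotypes
at random (target mean call rate 84%).  Two families descend from one
sub-population and three from another that drifted apart for ~100
generations, so genotype PCA separates the two groups — the structure
seen in real multi-origin breeding material.

Everything here is simulated; no real genotypes or phenotypes are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import SNPCatalogue, ValidationError
from .popsim import (
    MatingDesign,
    Population,
    TraitArchitecture,
    burnin_fisher_wright,
    genetic_values,
    mate_design,
)

TRAITS = ("SH", "SL", "SW")


@dataclass
class EmpiricalConfig:
    n_individuals: int = 349
    family_sizes: tuple[int, ...] = (70, 70, 70, 70, 69)  # 2 + 3 families
    n_markers: int = 2364
    n_marker_candidates: int = 9000
    n_qtl: int = 300
    n_chromosomes: int = 10
    chrom_mb: float = 10.0
    burnin_size: int = 500
    burnin_generations: int = 1000
    divergence_generations: int = 100
    missing_rate: float = 0.16
    maf_min: float = 0.05
    # trait targets: additive variance, heritability, population mean (mm)
    sigma_a2: dict = field(default_factory=lambda: {"SH": 14.58, "SL": 16.30, "SW": 2.66})
    h2: dict = field(default_factory=lambda: {"SH": 0.48, "SL": 0.48, "SW": 0.36})
    means: dict = field(default_factory=lambda: {"SH": 68.0, "SL": 72.0, "SW": 18.0})
    genetic_correlation: float = 0.6
    family_env_sd_frac: float = 0.05  # common-environment SD as fraction of sigma_P


@dataclass
class EmpiricalDataset:
    genotypes: np.ndarray  # 349 x 2364, 0/1/2 with NaN missing
    phenotypes: pd.DataFrame  # id, family, SH, SL, SW
    families: np.ndarray
    tbv: pd.DataFrame  # true breeding values per trait (simulation truth)
    pedigree: pd.DataFrame
    marker_info: pd.DataFrame  # chrom, pos per marker column
    group: np.ndarray  # 0 = full-sib-origin families, 1 = bi-parental-origin


def _map_only_catalogue(cfg: EmpiricalConfig, rng) -> SNPCatalogue:
    """Loci placed uniformly on a physical map, no nucleotide sequence."""
    n_loci = cfg.n_marker_candidates + cfg.n_qtl
    chrom_len = int(cfg.chrom_mb * 1e6)
    chroms = rng.integers(0, cfg.n_chromosomes, size=n_loci)
    pos = rng.integers(0, chrom_len, size=n_loci)
    df = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chroms],
        "pos": pos,
        "ref": np.zeros(n_loci, dtype=np.uint8),
        "alt": np.full(n_loci, 2, dtype=np.uint8),
        "freq": rng.uniform(0.05, 0.95, size=n_loci),
    })
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    df = df.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return SNPCatalogue(df)


def synth_empirical_dataset(
    config: EmpiricalConfig | None = None,
    seed: int | None = None,
) -> EmpiricalDataset:
    """Simulate the 5-family stand-in dataset (see module docstring)."""
    cfg = config or EmpiricalConfig()
    rng = np.random.default_rng(seed)
    cat = _map_only_catalogue(cfg, rng)

    base = burnin_fisher_wright(
        cat, cfg.burnin_generations, cfg.burnin_size,
        mutation_rate=1e-5, seed=int(rng.integers(2**31)),
    )
    # two diverged sub-populations: full-sib-family origin vs bi-parental origin
    half = base.n // 2
    sub = []
    for gi, rows in enumerate((np.arange(half), np.arange(half, base.n))):
        pop = base.subset_individuals(rows)
        pop = burnin_fisher_wright(
            pop, cfg.divergence_generations, half - half % 2,
            mutation_rate=1e-5, seed=int(rng.integers(2**31)),
        )
        pop.ids = pop.ids + 1000 * (gi + 1)  # keep ids unique across groups
        sub.append(pop)

    n_fam_a, n_fam_b = 2, len(cfg.family_sizes) - 2
    size = max(cfg.family_sizes)
    off_a = mate_design(sub[0], MatingDesign(n_fam_a, n_fam_a, n_fam_a, size, "F1"),
                        seed=int(rng.integers(2**31)), id_offset=10_000)
    off_b = mate_design(sub[1], MatingDesign(n_fam_b, n_fam_b, n_fam_b, size, "F1"),
                        seed=int(rng.integers(2**31)), id_offset=20_000)
    off_b.family = off_b.family + n_fam_a
    # honour per-family sizes
    keep = []
    for fam, want in enumerate(cfg.family_sizes):
        pool = off_a if fam < n_fam_a else off_b
        rows = np.flatnonzero(pool.family == fam)[:want]
        keep.append((pool, rows))
    hap = np.concatenate([p.haplotypes[r] for p, r in keep])
    ids = np.concatenate([p.ids[r] for p, r in keep])
    fams = np.concatenate([p.family[r] for p, r in keep])
    sires = np.concatenate([p.sire[r] for p, r in keep])
    dams = np.concatenate([p.dam[r] for p, r in keep])
    pop = Population(hap, off_a.loci, ids, sires, dams, fams, "F1")
    group = (fams >= n_fam_a).astype(int)

    # marker panel: segregating candidates at MAF > maf_min among the 349
    f = pop.allele_freqs()
    n_loci = len(pop.loci)
    is_qtl = np.zeros(n_loci, dtype=bool)
    qtl_cols = rng.choice(n_loci, size=cfg.n_qtl, replace=False)
    is_qtl[qtl_cols] = True
    seg = (np.minimum(f, 1 - f) > cfg.maf_min) & ~is_qtl
    cand = np.flatnonzero(seg)
    if cand.size < cfg.n_markers:
        raise ValidationError(
            f"only {cand.size} segregating markers; increase candidates")
    marker_cols = np.sort(rng.choice(cand, size=cfg.n_markers, replace=False))

    # three correlated traits from a shared QTL set
    k = len(TRAITS)
    R = np.full((k, k), cfg.genetic_correlation)
    np.fill_diagonal(R, 1.0)
    effects = rng.standard_normal((cfg.n_qtl, k)) @ np.linalg.cholesky(R).T
    tbv = {}
    phen = {}
    for t, trait in enumerate(TRAITS):
        arch = TraitArchitecture(np.sort(qtl_cols), effects[:, t][np.argsort(qtl_cols)],
                                 np.zeros(cfg.n_qtl))
        raw, _ = genetic_values(pop, arch)
        target_va = cfg.sigma_a2[trait]
        raw = raw - raw.mean()
        scale = np.sqrt(target_va / raw.var())
        bv = raw * scale
        h2 = cfg.h2[trait]
        ve = target_va * (1 - h2) / h2
        sp = np.sqrt(target_va + ve)
        fam_env = rng.normal(0, cfg.family_env_sd_frac * sp, size=len(cfg.family_sizes))
        phen[trait] = (cfg.means[trait] + bv + fam_env[fams]
                       + rng.normal(0, np.sqrt(ve), size=pop.n))
        tbv[trait] = bv

    X = pop.genotypes()[:, marker_cols].astype(float)
    miss = rng.random(X.shape) < cfg.missing_rate
    X[miss] = np.nan

    phenotypes = pd.DataFrame({"id": ids, "family": fams, **phen})
    parents = pd.concat([s.pedigree_frame() for s in sub], ignore_index=True)
    pedigree = pd.concat([parents, pop.pedigree_frame()], ignore_index=True)
    pedigree = pedigree.drop_duplicates("id", keep="first").reset_index(drop=True)
    marker_info = pd.DataFrame({
        "chrom": pop.loci.chrom[marker_cols],
        "pos": pop.loci.pos_bp[marker_cols],
    })
    return EmpiricalDataset(
        X, phenotypes, fams, pd.DataFrame(tbv), pedigree, marker_info, group,
    )
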