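"""End-to-end simulation scenarios and the experiment orchestrator.

Three study designs are wired through the genome -> burn-in -> mating ->
model -> evaluation pipeline:

* a population-based design (100 sires x 100 dams, 20 offspring per pair,
  two phenotyped generations) genotyped on density-matched marker panels
  (HD ~250/Mb evenly spaced, MD ~50/Mb from BsaXI-tag SNPs, LD ~5/Mb from
  RTR-tag SNPs);
* a family-based design (20 full-sib families x 50 from 10 sires and 10
  dams) on a fixed 2,364-marker reduced-representation panel;
* the same family design with 5 families and dominance variance.

Genome size is desk-scaled (tens of Mb) with per-Mb marker and QTL
densities preserved; see the methods note for the scaling argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome as gn
from .evaluation import CVScheme, cross_validate, over_generation_eval
from .genome import ValidationError
from .models import MODEL_REGISTRY, MarkerLasso, PedigreeBLUP
from .popsim import (
    MatingDesign,
    Population,
    SIMULATION_1,
    SIMULATION_2,
    SIMULATION_3,
    TraitArchitecture,
    burnin_fisher_wright,
    genetic_values,
    mate_design,
    simulate_phenotypes,
)

QTL_PER_MB = 5000.0 / 970.0  # genome-wide QTL count scaled per Mb
PANEL_DENSITIES = {"HD": 250.0, "MD": 50.0, "LD": 5.0}  # markers per Mb


def _subcatalogue(catalogue: gn.SNPCatalogue, idx: np.ndarray) -> gn.SNPCatalogue:
    return gn.SNPCatalogue(catalogue.loci.iloc[np.sort(idx)].reset_index(drop=True))


def _segregating(pop: Population, maf_min: float) -> np.ndarray:
    f = pop.allele_freqs()
    return np.minimum(f, 1 - f) >= maf_min


@dataclass
class PopulationScenario:
    """Simulation-1 style dataset: two phenotyped generations, several
    marker panels (column indices into the shared locus set)."""

    pop_g1: Population
    pop_g2: Population
    panels: dict[str, np.ndarray]
    arch: TraitArchitecture
    tbv_g1: np.ndarray
    tbv_g2: np.ndarray

    def genotypes(self, panel: str, generation: str = "G1") -> np.ndarray:
        pop = self.pop_g1 if generation == "G1" else self.pop_g2
        return pop.genotypes()[:, self.panels[panel]].astype(float)


def simulate_population_scenario(
    seed: int,
    genome_mb: float = 50.0,
    n_chromosomes: int = 5,
    gc_content: float = 0.35,
    snp_rate: float = 0.02,
    panels: tuple[str, ...] = ("MD", "LD"),
    n_qtl: int | None = None,
    burnin_size: int = 500,
    burnin_generations: int = 1000,
    mutation_rate: float = 1e-5,
    cm_per_mb: float = 1.0,
    design: MatingDesign = SIMULATION_1,
    maf_min: float = 0.05,
    hd_per_mb: float = PANEL_DENSITIES["HD"],
) -> PopulationScenario:
    """Build a population-based dataset with tag-derived marker panels.

    MD is every segregating (MAF >= ``maf_min`` after burn-in) SNP inside
    a BsaXI tag, LD every segregating SNP inside an RTR tag — the panel
    definitions of a 2b-RAD assay; their per-Mb densities emerge from the
    base composition.  HD is ``hd_per_mb`` x Mb SNPs chosen by even
    genomic spacing.  Only loci that can enter a panel (or are QTLs) are
    tracked through the burn-in.
    """
    rng = np.random.default_rng(seed)
    chrom_len = int(genome_mb * 1e6 / n_chromosomes)
    g = gn.simulate_genome(n_chromosomes, chrom_len, gc_content,
                           seed=int(rng.integers(2**31)))
    cat = gn.inject_snps(g, snp_rate, seed=int(rng.integers(2**31)))
    tags = gn.find_bsaxi_tags(g)
    rtr = gn.rtr_filter(tags, g)
    in_tags = gn._snps_in_tags(cat, tags)
    in_rtr = gn._snps_in_tags(cat, rtr)

    if n_qtl is None:
        n_qtl = max(10, int(round(QTL_PER_MB * genome_mb)))
    qtl_global = rng.choice(len(cat), size=n_qtl, replace=False)

    cand: dict[str, np.ndarray] = {}
    for p in panels:
        if p == "HD":
            pool = np.setdiff1d(np.arange(len(cat)), qtl_global)
            gpos = _global_positions(cat)
            target = int(round(hd_per_mb * genome_mb))
            cand[p] = gn._even_subset(pool, gpos[pool],
                                      min(2 * target, pool.size))
        else:
            pool = in_tags if p == "MD" else in_rtr
            cand[p] = np.setdiff1d(pool, qtl_global)

    union = np.unique(np.concatenate([qtl_global] + list(cand.values())))
    local = {int(gidx): i for i, gidx in enumerate(union)}
    subcat = _subcatalogue(cat, union)

    base = burnin_fisher_wright(
        subcat, burnin_generations, burnin_size, mutation_rate, cm_per_mb,
        seed=int(rng.integers(2**31)), founder_init="diploid",
    )
    seg = _segregating(base, maf_min)

    panel_cols: dict[str, np.ndarray] = {}
    for p in panels:
        cols = np.array([local[int(i)] for i in cand[p]])
        cols = np.sort(cols[seg[cols]])
        if p == "HD":
            want = min(int(round(hd_per_mb * genome_mb)), cols.size)
            gpos = _global_positions(subcat)
            cols = gn._even_subset(cols, gpos[cols], want)
        if cols.size == 0:
            warnings.warn(f"panel {p} is empty after burn-in")
        panel_cols[p] = cols

    g1 = mate_design(base, design, seed=int(rng.integers(2**31)))
    g2_design = MatingDesign(design.n_sires, design.n_dams, design.n_families,
                             design.n_offspring, "G2")
    g2 = mate_design(g1, g2_design, seed=int(rng.integers(2**31)))

    qtl_cols = np.array(sorted(local[int(i)] for i in qtl_global))
    arch = TraitArchitecture(
        qtl_cols,
        rng.normal(0.0, 1.0, size=qtl_cols.size),
        np.zeros(qtl_cols.size),
    )
    tbv1, _ = genetic_values(g1, arch)
    tbv2, _ = genetic_values(g2, arch)
    return PopulationScenario(g1, g2, panel_cols, arch, tbv1, tbv2)


def _global_positions(cat: gn.SNPCatalogue) -> np.ndarray:
    offsets, total = {}, 0
    for chrom, size in (cat.loci.groupby("chrom", sort=False).pos.max() + 1).items():
        offsets[chrom] = total
        total += int(size)
    return cat.loci.pos.to_numpy() + cat.loci.chrom.map(offsets).to_numpy()


@dataclass
class FamilyDataset:
    """A phenotype-ready family-structured dataset."""

    X: np.ndarray  # individuals x markers, 0/1/2
    families: np.ndarray
    tbv: np.ndarray
    dominance: np.ndarray | None
    ids: np.ndarray
    pedigree: pd.DataFrame  # parents first, then offspring


@dataclass
class FamilyScenarioBase:
    """Shared base (genome + burn-in + marker panel + QTL effects) from
    which the family-based designs are drawn."""

    base_pop: Population
    marker_cols: np.ndarray
    arch: TraitArchitecture
    dominance_effects: np.ndarray  # raw N(0,1), used by the dominance design
    _rng: np.random.Generator = field(repr=False, default=None)

    def _dataset(self, design: MatingDesign, with_dominance: bool) -> FamilyDataset:
        seed = int(self._rng.integers(2**31))
        off = mate_design(self.base_pop, design, seed=seed)
        arch = self.arch
        if with_dominance:
            arch = TraitArchitecture(self.arch.qtl_idx, self.arch.additive,
                                     self.dominance_effects, 0.3)
        tbv, dom = genetic_values(off, arch)
        X = off.genotypes()[:, self.marker_cols].astype(float)
        parents = self.base_pop.pedigree_frame()
        ped = pd.concat([parents, off.pedigree_frame()], ignore_index=True)
        return FamilyDataset(X, off.family, tbv,
                             dom if with_dominance else None, off.ids, ped)

    def family_dataset(self, n_families: int = 20, n_offspring: int = 50,
                       with_dominance: bool = False) -> FamilyDataset:
        if n_families == 20:
            design = SIMULATION_2
        elif n_families == 5 and with_dominance:
            design = SIMULATION_3
        else:
            per_sex = max(2, (n_families + 1) // 2)
            design = MatingDesign(per_sex, per_sex, n_families, n_offspring)
        return self._dataset(design, with_dominance)


def simulate_family_base(
    seed: int,
    genome_mb: float = 50.0,
    n_chromosomes: int = 5,
    gc_content: float = 0.35,
    snp_rate: float = 0.02,
    n_markers: int = 2364,
    n_qtl: int | None = None,
    burnin_size: int = 500,
    burnin_generations: int = 1000,
    mutation_rate: float = 1e-5,
    cm_per_mb: float = 1.0,
    maf_min: float = 0.05,
) -> FamilyScenarioBase:
    """Genome, burn-in and a fixed reduced-representation marker panel for
    the family-based designs.

    The ``n_markers`` panel is drawn from segregating BsaXI-tag SNPs (the
    marker count and sample sizes are kept at study scale; the genome is
    desk-scaled, so the tag class is relaxed from RTR to all-tag SNPs —
    see the methods note).
    """
    rng = np.random.default_rng(seed)
    chrom_len = int(genome_mb * 1e6 / n_chromosomes)
    g = gn.simulate_genome(n_chromosomes, chrom_len, gc_content,
                           seed=int(rng.integers(2**31)))
    cat = gn.inject_snps(g, snp_rate, seed=int(rng.integers(2**31)))
    tags = gn.find_bsaxi_tags(g)
    in_tags = gn._snps_in_tags(cat, tags)

    if n_qtl is None:
        n_qtl = max(10, int(round(QTL_PER_MB * genome_mb)))
    qtl_global = rng.choice(len(cat), size=n_qtl, replace=False)
    cand = np.setdiff1d(in_tags, qtl_global)

    union = np.unique(np.concatenate([qtl_global, cand]))
    local = {int(gidx): i for i, gidx in enumerate(union)}
    subcat = _subcatalogue(cat, union)
    base = burnin_fisher_wright(
        subcat, burnin_generations, burnin_size, mutation_rate, cm_per_mb,
        seed=int(rng.integers(2**31)), founder_init="diploid",
    )
    seg = _segregating(base, maf_min)
    cand_cols = np.array([local[int(i)] for i in cand])
    cand_cols = cand_cols[seg[cand_cols]]
    if cand_cols.size < n_markers:
        warnings.warn(
            f"only {cand_cols.size} segregating tag SNPs for requested "
            f"{n_markers}-marker panel")
        marker_cols = np.sort(cand_cols)
    else:
        marker_cols = np.sort(rng.choice(cand_cols, size=n_markers,
                                         replace=False))
    qtl_cols = np.array(sorted(local[int(i)] for i in qtl_global))
    arch = TraitArchitecture(qtl_cols,
                             rng.normal(0.0, 1.0, size=qtl_cols.size),
                             np.zeros(qtl_cols.size))
    dom = rng.normal(0.0, 1.0, size=qtl_cols.size)
    return FamilyScenarioBase(base, marker_cols, arch, dom, rng)


# ---------------------------------------------------------------------------
# experiment orchestration


def make_models(
    names,
    niter: int = 1500,
    burnin: int = 300,
    seed: int = 0,
    pedigree: pd.DataFrame | None = None,
) -> dict:
    """Instantiate estimators by registry name with shared MCMC settings."""
    out = {}
    for i, name in enumerate(names):
        if name not in MODEL_REGISTRY:
            raise ValidationError(f"unknown model {name!r}; "
                                  f"choose from {sorted(MODEL_REGISTRY)}")
        rs = (seed + 7919 * i) & 0x7FFFFFFF
        if name in ("BayesA", "BayesB", "BL"):
            cls = MODEL_REGISTRY[name]
            out[name] = cls(niter=niter, burnin=burnin, random_state=rs)
        elif name == "LASSO":
            out[name] = MarkerLasso(random_state=rs)
        elif name == "BLUP":
            out[name] = PedigreeBLUP(pedigree=pedigree)
        else:
            out[name] = MODEL_REGISTRY[name]()
    return out


_CONFIG_KEYS = {
    "scenario", "n_replicates", "h2", "methods", "panels", "n_families",
    "cv", "mcmc", "sizes", "seed", "over_generation", "dominance_share",
}


def run_experiment(config: dict) -> pd.DataFrame:
    """Run a scenario grid (panels x h2 x methods, or families x h2 x
    methods) and return a long-format results table.

    Config keys: scenario ("simulation1"|"simulation2"|"simulation3"),
    n_replicates, h2 (list), methods (list), panels (sim1), n_families
    (sim2), cv {n_folds, n_repeats}, mcmc {niter, burnin}, sizes (builder
    kwargs), seed, over_generation (sim1 flag), dominance_share (sim3).
    Unknown keys are rejected.
    """
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    scenario = config.get("scenario", "simulation1")
    n_rep = int(config.get("n_replicates", 1))
    h2_list = list(config.get("h2", [0.3]))
    methods = list(config.get("methods", ["G-BLUP", "BayesA"]))
    cv = config.get("cv", {})
    scheme = CVScheme(n_folds=int(cv.get("n_folds", 5)),
                      n_repeats=int(cv.get("n_repeats", 1)))
    mcmc = config.get("mcmc", {})
    niter = int(mcmc.get("niter", 1500))
    nburn = int(mcmc.get("burnin", 300))
    sizes = dict(config.get("sizes", {}))
    master = int(config.get("seed", 0))
    ss = np.random.SeedSequence(master)
    rep_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                 for s in ss.spawn(n_rep)]

    rows = []
    for rep, rseed in enumerate(rep_seeds):
        if scenario == "simulation1":
            panels = tuple(config.get("panels", ("MD", "LD")))
            data = simulate_population_scenario(rseed, panels=panels, **sizes)
            for h2 in h2_list:
                phen = simulate_phenotypes(data.tbv_g1, h2, seed=rseed + 17)
                for panel in panels:
                    X = data.genotypes(panel, "G1")
                    models = make_models(methods, niter, nburn, rseed)
                    scheme_r = CVScheme(scheme.n_folds, scheme.n_repeats,
                                        seed=rseed + 23)
                    res = cross_validate(X, phen.phenotype, models,
                                         scheme_r, tbv=data.tbv_g1)
                    res["panel"] = panel
                    res["h2"] = h2
                    res["replicate"] = rep
                    res["generation"] = "G1"
                    rows.append(res)
                    if config.get("over_generation"):
                        X2 = data.genotypes(panel, "G2")
                        models = make_models(methods, niter, nburn, rseed)
                        og = over_generation_eval(X, phen.phenotype, X2,
                                                  data.tbv_g2, models)
                        og["panel"] = panel
                        og["h2"] = h2
                        og["replicate"] = rep
                        og["generation"] = "G1->G2"
                        rows.append(og)
        elif scenario in ("simulation2", "simulation3"):
            base = simulate_family_base(rseed, **sizes)
            dom = scenario == "simulation3"
            fam_counts = (list(config.get("n_families", [20]))
                          if not dom else [5])
            data20 = base.family_dataset(20 if not dom else 5,
                                         with_dominance=dom)
            for nf in fam_counts:
                if nf == (5 if dom else 20):
                    data = data20
                else:
                    keep = np.isin(
                        data20.families,
                        np.random.default_rng(rseed + nf).choice(
                            np.unique(data20.families), nf, replace=False))
                    data = FamilyDataset(
                        data20.X[keep], data20.families[keep],
                        data20.tbv[keep],
                        None if data20.dominance is None
                        else data20.dominance[keep],
                        data20.ids[keep], data20.pedigree)
                for h2 in h2_list:
                    share = float(config.get("dominance_share", 0.3)) if dom else 0.0
                    phen = simulate_phenotypes(
                        data.tbv, h2, dominance=data.dominance,
                        dominance_share=share, seed=rseed + 31)
                    models = make_models(methods, niter, nburn, rseed,
                                         pedigree=data.pedigree)
                    scheme_r = CVScheme(scheme.n_folds, scheme.n_repeats,
                                        seed=rseed + 37)
                    # simulated phenotypes carry no family environmental
                    # term, so no family fixed effect is fitted here
                    res = cross_validate(data.X, phen.phenotype, models,
                                         scheme_r, tbv=data.tbv,
                                         ids=data.ids)
                    res["n_families"] = nf
                    res["h2"] = h2
                    res["replicate"] = rep
                    rows.append(res)
        else:
            raise ValidationError(f"unknown scenario {scenario!r}")
    out = pd.concat(rows, ignore_index=True)
    return out


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) accuracy per scenario cell, one row per grid cell."""
    keys = [c for c in ("generation", "panel", "n_families", "h2", "method")
            if c in results.columns]
    g = results.groupby(keys, dropna=False)["accuracy"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "accuracy", "std": "sd", "count": "n"})
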