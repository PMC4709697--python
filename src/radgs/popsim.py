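"""Forward-in-time breeding-population simulation.

A neutral Fisher-Wright burn-in (discrete generations, random union of
gametes, Poisson recombination under the Haldane map function, symmetric
bi-allelic mutation) establishes mutation-drift-recombination equilibrium
LD; explicit mating designs then produce the phenotyped generations.

Haplotypes are stored as a dense ``(n, 2, L)`` uint8 array of alternate-
allele indicators; genotypes are alt-allele counts in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genome import SNPCatalogue, ValidationError


@dataclass
class LocusMap:
    """Ordered loci with physical and genetic-map coordinates."""

    chrom: np.ndarray  # str per locus
    pos_bp: np.ndarray  # int, 0-based
    pos_cm: np.ndarray  # within-chromosome genetic position, cM

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if not (len(self.chrom) == len(self.pos_bp) == len(self.pos_cm)):
            raise ValidationError("locus map columns must have equal length")
        # concatenated genetic coordinate (Morgans) used by the meiosis code
        self._first_idx = []
        coords = np.empty(len(self.chrom))
        offset = 0.0
        start = 0
        for c in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            m = self.pos_cm[idx] / 100.0
            if (np.diff(m) < 0).any():
                raise ValidationError("map positions must be non-decreasing")
            coords[idx] = offset + (m - m[0])
            offset += m[-1] - m[0]
            self._first_idx.append(start)
            start += idx.size
        self.morgans = coords
        self.total_morgans = float(offset)
        self.chrom_first = np.asarray(self._first_idx, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.chrom)

    @classmethod
    def from_catalogue(cls, catalogue: SNPCatalogue, cm_per_mb: float = 1.0) -> "LocusMap":
        df = catalogue.loci
        return cls(
            df.chrom.to_numpy(),
            df.pos.to_numpy(),
            df.pos.to_numpy() * cm_per_mb / 1e6,
        )

    def subset(self, idx: np.ndarray) -> "LocusMap":
        idx = np.asarray(idx)
        return LocusMap(self.chrom[idx], self.pos_bp[idx], self.pos_cm[idx])


@dataclass
class Individual:
    id: int
    sire: int | None
    dam: int | None
    family: int
    generation: str
    haplotypes: np.ndarray  # (2, L)

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class Population:
    """Diploid individuals genotyped at a shared locus set."""

    haplotypes: np.ndarray  # (n, 2, L) uint8
    loci: LocusMap
    ids: np.ndarray
    sire: np.ndarray  # id of sire, -1 for founders
    dam: np.ndarray
    family: np.ndarray  # -1 if not family-structured
    generation: str = "G0"
    sex: np.ndarray | None = None  # 0 = male, 1 = female

    def __post_init__(self) -> None:
        if self.haplotypes.shape[2] != len(self.loci):
            raise ValidationError("haplotype length must equal locus count")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValidationError("individual ids must be unique")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> np.ndarray:
        """Alt-allele dosage matrix, shape (n, L), values in {0,1,2}."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def individual(self, i: int) -> Individual:
        sire = int(self.sire[i])
        dam = int(self.dam[i])
        return Individual(
            int(self.ids[i]),
            None if sire < 0 else sire,
            None if dam < 0 else dam,
            int(self.family[i]),
            self.generation,
            self.haplotypes[i],
        )

    def subset_individuals(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return Population(
            self.haplotypes[idx],
            self.loci,
            self.ids[idx],
            self.sire[idx],
            self.dam[idx],
            self.family[idx],
            self.generation,
            None if self.sex is None else self.sex[idx],
        )

    def subset_loci(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return Population(
            self.haplotypes[:, :, idx],
            self.loci.subset(idx),
            self.ids,
            self.sire,
            self.dam,
            self.family,
            self.generation,
            self.sex,
        )

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "family": self.family,
                "generation": self.generation,
            }
        )


# ---------------------------------------------------------------------------
# meiosis


@njit(cache=True)
def _gamete_kernel(hap2d, rows, parents, phase, chrom_first, xo_idx, xo_off, out):
    n_rows = rows.shape[0]
    L = out.shape[1]
    C = chrom_first.shape[0]
    for gi in range(n_rows):
        g = rows[gi]
        p = parents[g]
        s = xo_off[gi]
        e = xo_off[gi + 1]
        for c in range(C):
            cstart = chrom_first[c]
            cend = chrom_first[c + 1] if c + 1 < C else L
            h = phase[g, c]
            seg = cstart
            while s < e and xo_idx[s] < cend:
                b = xo_idx[s]
                if b > seg:
                    out[g, seg:b] = hap2d[2 * p + h, seg:b]
                    seg = b
                h = 1 - h
                s += 1
            out[g, seg:cend] = hap2d[2 * p + h, seg:cend]


def _make_gametes(
    haplotypes: np.ndarray, parent_idx: np.ndarray, loci: LocusMap, rng: np.random.Generator
) -> np.ndarray:
    """Gamete formation for ``parent_idx`` (one gamete each).

    Crossover counts are Poisson(total map length); with no crossover
    interference the parental-origin process along the map is Markov, so
    switch points fall uniformly on the concatenated genetic map.
    Chromosomes assort independently via a fresh random phase at each
    chromosome start.  Segment copying runs in a numba kernel.
    """
    G = parent_idx.size
    L = len(loci)
    C = loci.chrom_first.size
    parent_idx = parent_idx.astype(np.int64)
    phase = rng.integers(0, 2, size=(G, C), dtype=np.uint8)
    if loci.total_morgans > 0:
        k = rng.poisson(loci.total_morgans, size=G)
    else:
        k = np.zeros(G, dtype=np.int64)
    hap2d = np.ascontiguousarray(haplotypes.reshape(-1, L))
    out = np.empty((G, L), dtype=np.uint8)
    # fast path: copy the phase-selected parental haplotype per chromosome
    bounds = np.append(loci.chrom_first, L)
    for c in range(C):
        s, e = bounds[c], bounds[c + 1]
        out[:, s:e] = hap2d[2 * parent_idx + phase[:, c], s:e]
    # gametes with crossovers are rebuilt segment-wise
    rows = np.flatnonzero(k > 0)
    if rows.size:
        kx = k[rows]
        total = int(kx.sum())
        u = rng.uniform(0.0, loci.total_morgans, size=total)
        loc = np.searchsorted(loci.morgans, u, side="left").astype(np.int64)
        g_idx = np.repeat(rows, kx)
        order = np.lexsort((loc, g_idx))
        xo_idx = loc[order]
        xo_off = np.zeros(rows.size + 1, dtype=np.int64)
        np.cumsum(kx, out=xo_off[1:])
        _gamete_kernel(hap2d, rows, parent_idx, phase,
                       loci.chrom_first, xo_idx, xo_off, out)
    return out


def make_gamete(pop: Population, parent: int, rng: np.random.Generator) -> np.ndarray:
    """A single gamete from individual ``parent`` (row index)."""
    return _make_gametes(pop.haplotypes, np.array([parent]), pop.loci, rng)[0]


def _mutate(haplotypes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Symmetric bi-allelic mutation, in place."""
    if rate <= 0:
        return
    size = haplotypes.size
    n_mut = rng.binomial(size, rate)
    if n_mut:
        # sampled with replacement: a (rare) duplicate hit flips twice,
        # a negligible deviation at realistic per-copy rates
        flat = rng.integers(0, size, size=n_mut)
        haplotypes.reshape(-1)[flat] ^= 1


# ---------------------------------------------------------------------------
# burn-in


def founders_from_catalogue(
    catalogue: SNPCatalogue,
    pop_size: int,
    cm_per_mb: float = 1.0,
    seed: int | None = None,
    init: str = "equilibrium",
) -> Population:
    """Founder population for the burn-in.

    ``init="equilibrium"``: haplotypes drawn independently at the
    catalogue's initial allele frequencies (linkage equilibrium).
    ``init="diploid"``: every founder carries the same two ancestral
    haplotypes — the state produced by injecting SNPs into a single
    diploidized reference, with each alternate allele phased onto one of
    the two copies at random.  All loci start at frequency 1/2 in complete
    (random-sign) LD, which burn-in recombination and drift then erode.
    """
    rng = np.random.default_rng(seed)
    loci = LocusMap.from_catalogue(catalogue, cm_per_mb)
    if init == "diploid":
        phase = rng.integers(0, 2, size=len(loci)).astype(np.uint8)
        hapA = phase
        hapB = 1 - phase
        hap = np.broadcast_to(
            np.stack([hapA, hapB]), (pop_size, 2, len(loci))
        ).copy()
    elif init == "equilibrium":
        freq = catalogue.loci.freq.to_numpy()
        hap = (rng.random((pop_size, 2, len(loci))) < freq).astype(np.uint8)
    else:
        raise ValidationError("init must be 'equilibrium' or 'diploid'")
    n = pop_size
    return Population(
        hap,
        loci,
        ids=np.arange(n),
        sire=np.full(n, -1),
        dam=np.full(n, -1),
        family=np.full(n, -1),
        generation="G0",
    )


def burnin_fisher_wright(
    founders: Population | SNPCatalogue,
    n_generations: int = 1000,
    pop_size: int = 500,
    mutation_rate: float = 1e-5,
    cm_per_mb: float = 1.0,
    seed: int | None = None,
    founder_init: str = "equilibrium",
) -> Population:
    """Neutral Fisher-Wright burn-in.

    Each generation, every offspring draws two parents uniformly at random
    (with replacement) and receives one recombinant gamete from each.
    Monomorphic loci may arise from drift and are retained.  Returns the
    final generation with balanced, randomly assigned sexes.
    """
    if pop_size <= 0:
        raise ValidationError("pop_size must be positive")
    if pop_size % 2:
        raise ValidationError("pop_size must be even")
    rng = np.random.default_rng(seed)
    if isinstance(founders, SNPCatalogue):
        founders = founders_from_catalogue(
            founders, pop_size, cm_per_mb, seed=rng.integers(2**31),
            init=founder_init,
        )
    if n_generations == 0:
        return founders
    hap = founders.haplotypes
    if hap.shape[0] != pop_size:
        # resample founders to the requested size
        idx = rng.integers(0, hap.shape[0], size=pop_size)
        hap = hap[idx]
    loci = founders.loci
    for _ in range(n_generations):
        sires = rng.integers(0, pop_size, size=pop_size)
        dams = rng.integers(0, pop_size, size=pop_size)
        g1 = _make_gametes(hap, sires, loci, rng)
        g2 = _make_gametes(hap, dams, loci, rng)
        hap = np.stack([g1, g2], axis=1)
        _mutate(hap, mutation_rate, rng)
    return Population(
        hap,
        loci,
        ids=np.arange(pop_size),
        sire=np.full(pop_size, -1),
        dam=np.full(pop_size, -1),
        family=np.full(pop_size, -1),
        generation=f"G{n_generations}",
        # balanced sexes (random assignment) so a design needing n/2
        # parents of each sex is always feasible
        sex=rng.permutation(np.repeat([0, 1], pop_size // 2)),
    )


# ---------------------------------------------------------------------------
# mating designs


@dataclass
class MatingDesign:
    """A batch of full-sib matings.

    ``n_families`` (sire, dam) pairs each produce ``n_offspring`` full sibs.
    Parents of each sex are drawn without replacement from the candidate
    pool; when ``n_families`` exceeds the number of parents per sex, each
    parent serves in multiple matings (distinct pairs enforced).
    """

    n_sires: int
    n_dams: int
    n_families: int
    n_offspring: int
    generation_label: str = "G1"


SIMULATION_1 = MatingDesign(100, 100, 100, 20, "G1")
SIMULATION_2 = MatingDesign(10, 10, 20, 50, "G1")
SIMULATION_3 = MatingDesign(5, 5, 5, 50, "G1")


def _pair_parents(
    sires: np.ndarray, dams: np.ndarray, n_families: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    uses = max(1, int(np.ceil(n_families / min(sires.size, dams.size))))
    for _ in range(200):
        s = np.concatenate([rng.permutation(sires) for _ in range(uses)])[: n_families]
        d = np.concatenate([rng.permutation(dams) for _ in range(uses)])[: n_families]
        pairs = set(zip(s.tolist(), d.tolist()))
        if len(pairs) == n_families:
            return list(zip(s.tolist(), d.tolist()))
    raise ValidationError("could not form distinct parent pairs")  # pragma: no cover


def mate_design(
    pop: Population,
    design: MatingDesign,
    seed: int | None = None,
    id_offset: int | None = None,
) -> Population:
    """Apply a full-sib mating design to ``pop`` and return the offspring
    generation with pedigree recorded (sire/dam ids refer to ``pop.ids``)."""
    rng = np.random.default_rng(seed)
    if pop.sex is None:
        sex = rng.integers(0, 2, size=pop.n)
    else:
        sex = pop.sex
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    if males.size < design.n_sires or females.size < design.n_dams:
        raise ValidationError(
            f"need {design.n_sires} males / {design.n_dams} females, "
            f"have {males.size} / {females.size}"
        )
    sires = rng.choice(males, size=design.n_sires, replace=False)
    dams = rng.choice(females, size=design.n_dams, replace=False)
    pairs = _pair_parents(sires, dams, design.n_families, rng)

    n_off = design.n_families * design.n_offspring
    sire_rows = np.repeat([p[0] for p in pairs], design.n_offspring)
    dam_rows = np.repeat([p[1] for p in pairs], design.n_offspring)
    fam = np.repeat(np.arange(design.n_families), design.n_offspring)
    g_s = _make_gametes(pop.haplotypes, sire_rows, pop.loci, rng)
    g_d = _make_gametes(pop.haplotypes, dam_rows, pop.loci, rng)
    hap = np.stack([g_s, g_d], axis=1)
    start = int(pop.ids.max()) + 1 if id_offset is None else id_offset
    return Population(
        hap,
        pop.loci,
        ids=np.arange(start, start + n_off),
        sire=pop.ids[sire_rows],
        dam=pop.ids[dam_rows],
        family=fam,
        generation=design.generation_label,
        sex=rng.integers(0, 2, size=n_off),
    )


# ---------------------------------------------------------------------------
# trait architecture and phenotypes


@dataclass
class TraitArchitecture:
    """QTL positions and allelic effects for one additive(+dominance) trait."""

    qtl_idx: np.ndarray  # indices into the population locus set
    additive: np.ndarray  # a_j ~ N(0, 1)
    dominance: np.ndarray  # d_j (zeros unless dominance enabled)
    dominance_ratio: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=np.int64)
        if len(np.unique(self.qtl_idx)) != len(self.qtl_idx):
            raise ValidationError("QTL indices must be unique")


def assign_qtl(
    n_loci: int,
    n_qtl: int = 5000,
    dominance_ratio: float = 0.0,
    seed: int | None = None,
) -> TraitArchitecture:
    """Choose ``n_qtl`` loci at random; allelic effects ~ N(0, 1).

    When ``dominance_ratio`` > 0 raw dominance effects are also drawn
    N(0, 1); they are rescaled to the target variance share when phenotypes
    are generated (the realized shares depend on the population)."""
    if n_qtl > n_loci:
        raise ValidationError("n_qtl exceeds the number of loci")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
    a = rng.normal(0.0, 1.0, size=n_qtl)
    d = rng.normal(0.0, 1.0, size=n_qtl) if dominance_ratio > 0 else np.zeros(n_qtl)
    return TraitArchitecture(idx, a, d, dominance_ratio)


def genetic_values(pop: Population, arch: TraitArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """True breeding values and raw dominance deviations.

    TBV_i = sum_j x_ij a_j with x in {0,1,2}; the dominance term adds d_j
    for each heterozygous QTL genotype.
    """
    if arch.qtl_idx.max(initial=-1) >= len(pop.loci):
        raise ValidationError("architecture refers to loci outside the population")
    X = pop.genotypes()[:, arch.qtl_idx].astype(float)
    tbv = X @ arch.additive
    dom = (X == 1.0) @ arch.dominance
    return tbv, dom


@dataclass
class PhenotypeSet:
    tbv: np.ndarray
    dominance: np.ndarray  # scaled dominance deviations
    env: np.ndarray
    phenotype: np.ndarray
    h2_target: float
    h2_realized: float
    var_additive: float
    var_dominance: float
    var_env: float


def simulate_phenotypes(
    tbv: np.ndarray,
    h2: float,
    dominance: np.ndarray | None = None,
    dominance_share: float = 0.0,
    seed: int | None = None,
    share_denominator: str = "phenotypic",
) -> PhenotypeSet:
    """Phenotypes = TBV + (scaled) dominance + Gaussian error.

    The error variance is calibrated from the realized additive variance of
    this sample: sigma_e^2 = V_A (1 - h2 - s) / h2 where ``s`` is the
    dominance share of phenotypic variance (0 without dominance).  With
    ``share_denominator="genetic"`` the additive and dominance shares are
    interpreted relative to total genetic variance instead.
    """
    if not 0 < h2 <= 1:
        raise ValidationError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    tbv = np.asarray(tbv, dtype=float)
    va = float(np.var(tbv))
    if va == 0:
        raise ValidationError("additive variance is zero; cannot calibrate phenotypes")
    dom = np.zeros_like(tbv)
    vd = 0.0
    if dominance is not None and dominance_share > 0:
        raw = np.asarray(dominance, dtype=float)
        vraw = float(np.var(raw))
        if vraw == 0:
            raise ValidationError("dominance deviations have zero variance")
        if share_denominator == "phenotypic":
            # V_A/V_P = h2, V_D/V_P = share
            if h2 + dominance_share >= 1:
                raise ValidationError("h2 + dominance share must be < 1")
            vp = va / h2
            vd = dominance_share * vp
        elif share_denominator == "genetic":
            # V_A/V_G = h2-slot share, V_D/V_G = share; V_G/V_P set so that
            # narrow-sense heritability stays V_A/V_P = h2
            vd = va * dominance_share / h2
            vp = va / h2
        else:
            raise ValidationError("share_denominator must be 'phenotypic' or 'genetic'")
        dom = raw * np.sqrt(vd / vraw)
        ve = vp - va - vd
        if ve <= 0:
            raise ValidationError("variance shares leave no room for error variance")
    else:
        if dominance is not None:
            dom = np.asarray(dominance, dtype=float)
            vd = float(np.var(dom))
        ve = va * (1 - h2) / h2
    env = rng.normal(0.0, np.sqrt(ve), size=tbv.size) if ve > 0 else np.zeros_like(tbv)
    phen = tbv + dom + env
    realized = va / float(np.var(phen)) if np.var(phen) > 0 else np.nan
    return PhenotypeSet(tbv, dom, env, phen, h2, realized, va, vd, float(ve))
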