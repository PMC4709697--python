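"""Synthetic genomes, SNP injection and in-silico type IIB restriction tags.

The type IIB enzyme BsaXI cuts on both sides of its bipartite recognition
site and excises a uniform-length fragment.  Written 5'->3' the tag is

    N10 - AC - N5 - CTCC - N8        (29 bases)

Reduced tag representation (RTR) libraries use selective adaptors with
5'-NNA-3' overhangs, which only ligate tags whose first base is A and whose
last base is T; under uniform base composition 1/16 of tags survive.

Coordinates are 0-based, half-open throughout; a SNP at position ``p`` lies
inside tag ``[s, s+29)`` iff ``s <= p < s+29``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAG_LEN = 29
BASES = np.array(["A", "C", "G", "T"])
_CODE = {b: i for i, b in enumerate(BASES)}
# offset -> required base code, forward-strand motif (AC at 10-11, CTCC at 17-20)
_FWD = {10: 0, 11: 1, 17: 1, 18: 3, 19: 1, 20: 1}
# reverse-complement motif seen on the forward strand: GGAG at 8-11, GT at 17-18
_REV = {8: 2, 9: 2, 10: 0, 11: 2, 17: 2, 18: 3}

FWD_REGEX = re.compile(r"(?=(.{10}AC.{5}CTCC.{8}))", re.S)
REV_REGEX = re.compile(r"(?=(.{8}GGAG.{5}GT.{10}))", re.S)


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class Genome:
    """A diploidized reference genome: named chromosomes over {A,C,G,T}.

    Sequences are stored as uint8 codes (A=0, C=1, G=2, T=3).
    """

    chromosomes: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        for _, seq in self.chromosomes:
            if seq.dtype != np.uint8 or seq.ndim != 1:
                raise ValidationError("sequences must be 1-D uint8 code arrays")
            if seq.size and seq.max() > 3:
                raise ValidationError("sequence codes must be in {0,1,2,3}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return int(sum(seq.size for _, seq in self.chromosomes))

    def sequence(self, name: str) -> np.ndarray:
        for n, seq in self.chromosomes:
            if n == name:
                return seq
        raise KeyError(name)

    def sequence_str(self, name: str) -> str:
        return "".join(BASES[self.sequence(name)])

    def base_composition(self) -> np.ndarray:
        """Realized genome-wide base frequencies in A,C,G,T order."""
        counts = np.zeros(4, dtype=np.int64)
        for _, seq in self.chromosomes:
            counts += np.bincount(seq, minlength=4)
        return counts / counts.sum()

    def to_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequence_str(n)), id=n, description="")
            for n in self.names
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        chroms = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
            codes = np.full(seq.size, 255, dtype=np.uint8)
            for b, c in _CODE.items():
                codes[seq == ord(b)] = c
            if (codes > 3).any():
                raise ValidationError(f"non-ACGT base in {rec.id}")
            chroms.append((rec.id, codes))
        return cls(chroms)

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Genome":
        chroms = []
        for name, s in seqs.items():
            try:
                codes = np.array([_CODE[b] for b in s.upper()], dtype=np.uint8)
            except KeyError as exc:  # pragma: no cover - message only
                raise ValidationError(f"non-ACGT base {exc} in {name}") from exc
            chroms.append((name, codes))
        return cls(chroms)


@dataclass
class SNPCatalogue:
    """Bi-allelic SNPs injected into a genome.

    ``loci`` columns: chrom, pos (0-based), ref, alt (codes 0..3), freq
    (initial alternate-allele frequency).
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "ref", "alt", "freq"}
        if not need <= set(self.loci.columns):
            raise ValidationError(f"catalogue needs columns {sorted(need)}")
        if len(self.loci):
            if (self.loci.ref == self.loci.alt).any():
                raise ValidationError("ref and alt alleles must differ")
            f = self.loci.freq.to_numpy()
            if (f <= 0).any() or (f >= 1).any():
                raise ValidationError("frequencies must lie strictly in (0,1)")
            for _, grp in self.loci.groupby("chrom", sort=False):
                if not grp.pos.is_monotonic_increasing:
                    raise ValidationError("positions must increase within a chromosome")

    def __len__(self) -> int:
        return len(self.loci)

    def to_tsv(self, path) -> None:
        df = self.loci.copy()
        df["ref"] = BASES[df.ref.to_numpy()]
        df["alt"] = BASES[df.alt.to_numpy()]
        df.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path) -> None:
        """Sites-only VCF (positions are 1-based there)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=radgs\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for i, row in enumerate(self.loci.itertuples(index=False)):
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\tsnp{i}\t{BASES[row.ref]}\t"
                    f"{BASES[row.alt]}\t.\tPASS\tAF={row.freq:.4f}\n"
                )


@dataclass
class RestrictionTag:
    chrom: str
    start: int  # 0-based; tag occupies [start, start+29)
    strand: str  # '+' or '-'
    sequence: str  # 5'->3' on its own strand
    is_rtr: bool = False


@dataclass
class MarkerPanel:
    """An ordered subset of SNP-catalogue rows used as a genotyping panel."""

    name: str
    loci: np.ndarray  # sorted unique integer indices into the catalogue
    density: float = field(default=np.nan)  # markers per Mb

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=np.int64)
        if self.loci.size and (
            (np.diff(self.loci) <= 0).any() or self.loci.min() < 0
        ):
            raise ValidationError("panel loci must be unique, sorted, non-negative")

    def __len__(self) -> int:
        return len(self.loci)

    def to_tsv(self, path, catalogue: SNPCatalogue) -> None:
        sub = catalogue.loci.iloc[self.loci][["chrom", "pos"]].copy()
        sub.insert(0, "index", self.loci)
        sub["panel"] = self.name
        sub.to_csv(path, sep="\t", index=False)


def simulate_genome(
    n_chromosomes: int,
    chrom_length: int,
    base_composition=None,
    seed: int | None = None,
) -> Genome:
    """Simulate a random genome with i.i.d. bases.

    ``base_composition`` may be a length-4 probability vector in A,C,G,T
    order, or a GC fraction (scalar); default uniform.  Deterministic for a
    fixed seed.
    """
    if n_chromosomes < 1:
        raise ValidationError("n_chromosomes must be >= 1")
    if chrom_length < 1000:
        raise ValidationError("chrom_length must be at least 1 kb")
    if base_composition is None:
        probs = np.full(4, 0.25)
    elif np.isscalar(base_composition):
        gc = float(base_composition)
        if not 0 < gc < 1:
            raise ValidationError("GC fraction must lie in (0,1)")
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    else:
        probs = np.asarray(base_composition, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or probs.sum() <= 0:
            raise ValidationError("composition must be 4 non-negative probabilities")
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    chroms = [
        (f"chr{i + 1}", rng.choice(4, size=chrom_length, p=probs).astype(np.uint8))
        for i in range(n_chromosomes)
    ]
    return Genome(chroms)


def inject_snps(
    genome: Genome,
    rate: float = 0.02,
    freq_model=None,
    seed: int | None = None,
) -> SNPCatalogue:
    """Inject bi-allelic SNPs at a per-base ``rate``.

    Each base independently hosts a SNP with probability ``rate``; the
    alternate allele is drawn uniformly from the three non-reference bases
    and its initial population frequency from ``freq_model`` (a callable
    ``f(rng, n) -> freqs``; default Uniform(0.05, 0.95)).
    """
    if not 0 < rate < 1:
        raise ValidationError("rate must lie strictly in (0,1)")
    rng = np.random.default_rng(seed)
    frames = []
    for name, seq in genome.chromosomes:
        n = rng.binomial(seq.size, rate)
        pos = np.sort(rng.choice(seq.size, size=n, replace=False))
        ref = seq[pos]
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        if freq_model is None:
            freq = rng.uniform(0.05, 0.95, size=n)
        else:
            freq = np.asarray(freq_model(rng, n), dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "ref": ref.astype(np.uint8),
                    "alt": alt.astype(np.uint8),
                    "freq": freq,
                }
            )
        )
    loci = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "freq"]
    )
    return SNPCatalogue(loci)


def _match_positions(seq: np.ndarray, motif: dict[int, int]) -> np.ndarray:
    L = seq.size
    if L < TAG_LEN:
        return np.empty(0, dtype=np.int64)
    n = L - TAG_LEN + 1
    ok = np.ones(n, dtype=bool)
    for off, code in motif.items():
        ok &= seq[off : off + n] == code
    return np.flatnonzero(ok).astype(np.int64)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def find_bsaxi_tags(genome: Genome, search_both_strands: bool = True) -> list[RestrictionTag]:
    """Locate all BsaXI tags (29-base N10-AC-N5-CTCC-N8 windows).

    Windows must fit entirely inside the chromosome (sites without a full
    flank are dropped).  With ``search_both_strands`` the reverse-complement
    motif (GGAG-N5-GT on the forward strand) is matched as well; a given
    start can match at most one strand, so no deduplication is needed.
    """
    if genome.total_length == 0:
        raise ValidationError("genome is empty")
    tags: list[RestrictionTag] = []
    for name, seq in genome.chromosomes:
        starts = _match_positions(seq, _FWD)
        for s in starts:
            window = seq[s : s + TAG_LEN]
            tags.append(RestrictionTag(name, int(s), "+", "".join(BASES[window])))
        if search_both_strands:
            for s in _match_positions(seq, _REV):
                window = _revcomp_codes(seq[s : s + TAG_LEN])
                tags.append(RestrictionTag(name, int(s), "-", "".join(BASES[window])))
    tags.sort(key=lambda t: (t.chrom, t.start, t.strand))
    return tags


def rtr_filter(tags: list[RestrictionTag], genome: Genome) -> list[RestrictionTag]:
    """Keep tags compatible with selective 5'-NNA-3' adaptors.

    On its own strand an RTR tag reads A-N9-AC-N5-CTCC-N7-T: first base A,
    last base T.  Returns new tag objects with ``is_rtr`` set.
    """
    names = set(genome.names)
    out = []
    for t in tags:
        if t.chrom not in names:
            raise ValidationError(f"tag chromosome {t.chrom!r} not in genome")
        seq = genome.sequence(t.chrom)
        if t.start < 0 or t.start + TAG_LEN > seq.size:
            raise ValidationError("tag does not fit inside its chromosome")
        if t.sequence[0] == "A" and t.sequence[-1] == "T":
            out.append(RestrictionTag(t.chrom, t.start, t.strand, t.sequence, True))
    return out


def tags_to_bed(tags: list[RestrictionTag], path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            label = "RTR" if t.is_rtr else "BsaXI"
            fh.write(f"{t.chrom}\t{t.start}\t{t.start + TAG_LEN}\t{label}\t0\t{t.strand}\n")


def _snps_in_tags(catalogue: SNPCatalogue, tags: list[RestrictionTag]) -> np.ndarray:
    """Indices of catalogue SNPs falling inside any tag interval."""
    starts_by_chrom: dict[str, np.ndarray] = {}
    for t in tags:
        starts_by_chrom.setdefault(t.chrom, [])
    for t in tags:
        starts_by_chrom[t.chrom].append(t.start)
    hit = np.zeros(len(catalogue), dtype=bool)
    for chrom, starts in starts_by_chrom.items():
        starts = np.unique(np.asarray(starts, dtype=np.int64))
        mask = catalogue.loci.chrom.to_numpy() == chrom
        pos = catalogue.loci.pos.to_numpy()[mask]
        # a SNP at p is inside [s, s+29) iff s in (p-29, p]
        lo = np.searchsorted(starts, pos - TAG_LEN, side="right")
        hi = np.searchsorted(starts, pos, side="right")
        hit[np.flatnonzero(mask)[hi > lo]] = True
    return np.flatnonzero(hit)


def build_marker_panels(
    snps: SNPCatalogue,
    tags: list[RestrictionTag],
    hd_size: int,
    ld_subsample: int | None = None,
    seed: int | None = None,
    exclude: np.ndarray | None = None,
) -> dict[str, MarkerPanel]:
    """Assemble the HD / MD / LD marker panels.

    HD: ``hd_size`` SNPs chosen by even genomic spacing.  MD: all SNPs
    inside BsaXI tags.  LD: SNPs inside RTR tags, optionally randomly
    subsampled to ``ld_subsample`` loci.  ``exclude`` removes loci (e.g.
    QTLs) from every panel before selection.
    """
    if len(snps) == 0:
        raise ValidationError("empty SNP catalogue")
    if hd_size > len(snps):
        raise ValidationError("hd_size exceeds catalogue size")
    rng = np.random.default_rng(seed)
    keep = np.ones(len(snps), dtype=bool)
    if exclude is not None and len(exclude):
        keep[np.asarray(exclude, dtype=np.int64)] = False
    candidates = np.flatnonzero(keep)

    # genome-wide linear coordinate for even spacing
    offsets, total = {}, 0
    chrom_sizes = snps.loci.groupby("chrom", sort=False).pos.max() + 1
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = total
        total += int(size)
    gpos = snps.loci.pos.to_numpy() + snps.loci.chrom.map(offsets).to_numpy()

    hd = _even_subset(candidates, gpos[candidates], hd_size)

    in_tags = _snps_in_tags(snps, tags)
    rtr_tags = [t for t in tags if t.is_rtr]
    in_rtr = _snps_in_tags(snps, rtr_tags)
    md = np.intersect1d(in_tags, candidates)
    ld = np.intersect1d(in_rtr, candidates)
    if md.size == 0:
        warnings.warn("no SNPs fall inside BsaXI tags; MD panel is empty")
    if ld.size == 0:
        warnings.warn("no SNPs fall inside RTR tags; LD panel is empty")
    if ld_subsample is not None and ld.size > ld_subsample:
        ld = np.sort(rng.choice(ld, size=ld_subsample, replace=False))

    mb = total / 1e6
    return {
        "HD": MarkerPanel("HD", hd, density=hd.size / mb),
        "MD": MarkerPanel("MD", md, density=md.size / mb),
        "LD": MarkerPanel("LD", ld, density=ld.size / mb),
    }


def _even_subset(indices: np.ndarray, gpos: np.ndarray, size: int) -> np.ndarray:
    """Pick ``size`` loci whose genome coordinates are as evenly spaced as possible."""
    if size > indices.size:
        raise ValidationError("requested panel larger than candidate set")
    if size == indices.size:
        return np.sort(indices)
    targets = np.linspace(gpos.min(), gpos.max(), size)
    order = np.argsort(gpos)
    sorted_pos = gpos[order]
    picks = np.searchsorted(sorted_pos, targets)
    picks = np.clip(picks, 0, sorted_pos.size - 1)
    # snap to nearest of the two neighbours, then deduplicate greedily
    left = np.clip(picks - 1, 0, sorted_pos.size - 1)
    use_left = np.abs(sorted_pos[left] - targets) < np.abs(sorted_pos[picks] - targets)
    picks = np.where(use_left, left, picks)
    picks = np.unique(picks)
    # backfill duplicates removed by unique with unused loci closest to gaps
    while picks.size < size:
        unused = np.setdiff1d(np.arange(sorted_pos.size), picks, assume_unique=False)
        need = size - picks.size
        picks = np.sort(np.concatenate([picks, unused[:need]]))
    return np.sort(indices[order[picks]])


def brute_force_tag_scan(sequence: str, search_both_strands: bool = True) -> list[tuple[int, str]]:
    """Independent regex scan returning (start, strand); oracle for find_bsaxi_tags."""
    hits = [(m.start(1), "+") for m in FWD_REGEX.finditer(sequence)]
    if search_both_strands:
        hits += [(m.start(1), "-") for m in REV_REGEX.finditer(sequence)]
    return sorted(hits)
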