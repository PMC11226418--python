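"""Synthetic mutagenesis studies with known ground truth.

The generator emulates the data structure of a resequenced EMS population:

* a reference genome of placed chromosomes plus unplaced scaffolds,
* protein-coding gene models with guaranteed-open reading frames (ATG,
  sense codons, single terminal stop) so effect classification is exact,
* fixed background divergence between the mutagenized cultivar and the
  reference line (homozygous alternate in every sample),
* individual wild-type noise (one control plant deviating),
* per-mutant private EMS mutations drawn from a configurable substitution
  spectrum biased toward C/G->T/A transitions, with Bernoulli zygosity,
* optional mutant-shared sites, scaffold mutations and missing genotypes.

Every planted site is recorded in a :class:`GroundTruth` object so the
filtering cascade's output can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from emsift.variant_io import (
    MISSING,
    GeneModel,
    Genome,
    Genotype,
    GenotypeLike,
    VariantSite,
    write_gene2go,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_population",
    "simulate_study",
    "write_study",
]

#: The six strand-symmetric substitution classes, transitions first.
SPECTRUM_CLASSES = (
    "C/G>T/A", "T/A>C/G",            # transitions
    "C/G>A/T", "T/A>A/T", "T/A>G/C", "C/G>G/C",  # transversions
)

# ref base -> alt base per class
_CLASS_SUBS = {
    "C/G>T/A": {"C": "T", "G": "A"},
    "T/A>C/G": {"T": "C", "A": "G"},
    "C/G>A/T": {"C": "A", "G": "T"},
    "T/A>A/T": {"T": "A", "A": "T"},
    "T/A>G/C": {"T": "G", "A": "C"},
    "C/G>G/C": {"C": "G", "G": "C"},
}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic mutagenesis experiment.

    Defaults describe a desk-scale study: 18 placed chromosomes of 1 Mb,
    five wild-type controls, nine mutants whose per-line mutation loads
    are drawn log-uniformly (mutant libraries show order-of-magnitude
    spread between lines), a 60% transition fraction with three quarters
    of transitions being C/G->T/A (the EMS signature), and one third
    homozygous mutations (an M2 selfing generation fixes roughly a third
    of the detectable induced alleles).
    """

    n_placed: int = 18
    placed_length: int = 1_000_000
    placed_lengths: tuple[int, ...] | None = None  # overrides placed_length
    n_unplaced: int = 2
    unplaced_length: int = 50_000
    n_wildtype: int = 5
    n_mutant: int = 9
    background_rate: float = 5e-4       # WT-vs-reference divergence per bp
    wt_noise_rate: float = 5e-5         # individual WT differences per bp
    ems_count_range: tuple[int, int] = (500, 5_000)  # log-uniform per mutant
    ems_counts: tuple[int, ...] | None = None        # explicit per-mutant counts
    transition_fraction: float = 0.6
    cg_ta_share: float = 0.75           # share of transitions that are C/G->T/A
    transversion_weights: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.1)
    homozygous_fraction: float = 1 / 3
    missing_rate: float = 0.0
    shared_mutant_fraction: float = 0.0  # extra sites shared by all mutants
    scaffold_ems_fraction: float = 0.02  # extra per-mutant sites on scaffolds
    genes_per_mb: float = 30.0
    cds_exon_length: int = 150           # two exons per gene; must be multiple of 3
    intron_length: int = 100
    n_go_terms: int = 50
    go_terms_per_gene_mean: float = 2.0

    def __post_init__(self) -> None:
        for name in ("background_rate", "wt_noise_rate", "transition_fraction",
                     "cg_ta_share", "homozygous_fraction", "missing_rate",
                     "shared_mutant_fraction", "scaffold_ems_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.placed_lengths is not None and len(self.placed_lengths) != self.n_placed:
            raise ValueError("placed_lengths must have n_placed entries")
        lengths = self.chromosome_lengths()
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("all lengths must be positive")
        if self.cds_exon_length % 3:
            raise ValueError("cds_exon_length must be a multiple of 3")
        if self.ems_counts is not None and len(self.ems_counts) != self.n_mutant:
            raise ValueError("ems_counts must have n_mutant entries")

    # naming follows the R2..R10 mutant / R11..R15 control convention
    @property
    def mutant_ids(self) -> list[str]:
        return [f"R{i}" for i in range(2, 2 + self.n_mutant)]

    @property
    def wildtype_ids(self) -> list[str]:
        return [f"R{i}" for i in range(2 + self.n_mutant, 2 + self.n_mutant + self.n_wildtype)]

    @property
    def sample_roles(self) -> dict[str, str]:
        roles = {m: "mutant" for m in self.mutant_ids}
        roles.update({w: "wildtype" for w in self.wildtype_ids})
        return roles

    def chromosome_lengths(self) -> dict[str, int]:
        placed = self.placed_lengths or (self.placed_length,) * self.n_placed
        out = {f"Chr{i + 1:02d}": int(l) for i, l in enumerate(placed)}
        out.update({f"scaffold_{i + 1}": self.unplaced_length for i in range(self.n_unplaced)})
        return out

    @property
    def placed_ids(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_placed)]

    def spectrum_probs(self) -> np.ndarray:
        ts = self.transition_fraction
        tw = np.asarray(self.transversion_weights, dtype=float)
        tw = tw / tw.sum()
        return np.array([ts * self.cg_ta_share, ts * (1 - self.cg_ta_share),
                         *((1 - ts) * tw)])


@dataclass
class GroundTruth:
    """Planted site registry; all coordinate tuples are (chrom, pos, ref, alt)."""

    ems_sites: dict[str, list[tuple[str, int, str, str, str]]] = field(default_factory=dict)
    unplaced_ems_sites: dict[str, list[tuple[str, int, str, str, str]]] = field(default_factory=dict)
    background_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    wt_noise_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    shared_mutant_sites: list[tuple[str, int, str, str]] = field(default_factory=list)

    def ems_keys(self, mutant: str) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, _ in self.ems_sites.get(mutant, [])}

    def n_planted(self) -> int:
        return (
            sum(len(v) for v in self.ems_sites.values())
            + sum(len(v) for v in self.unplaced_ems_sites.values())
            + len(self.background_sites)
            + len(self.wt_noise_sites)
            + len(self.shared_mutant_sites)
        )

    def to_json(self) -> str:
        return json.dumps({"version": 1, **asdict(self)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            ems_sites={m: [tuple(x) for x in v] for m, v in raw["ems_sites"].items()},
            unplaced_ems_sites={m: [tuple(x) for x in v]
                                for m, v in raw["unplaced_ems_sites"].items()},
            background_sites=[tuple(x) for x in raw["background_sites"]],
            wt_noise_sites=[tuple(x) for x in raw["wt_noise_sites"]],
            shared_mutant_sites=[tuple(x) for x in raw["shared_mutant_sites"]],
        )


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def _random_cds_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + sense codons + one stop: an open reading frame by construction."""
    if n_codons < 3:
        raise ValueError("CDS needs at least 3 codons")
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(body) + str(stop)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Genome, list[GeneModel]]:
    """Uniform-random sequences with non-overlapping two-exon genes.

    Gene CDS sequences are spliced into the chromosome so that every model
    translates without internal stop codons (strand-aware). GO terms are
    attached per gene from a Poisson number of draws over the term pool.
    """
    lengths = config.chromosome_lengths()
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: dict[str, bytearray] = {}
    for chrom, length in lengths.items():
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        sequences[chrom] = bytearray(base_lut[codes].tobytes())

    gene_models: list[GeneModel] = []
    exon = config.cds_exon_length
    intron = config.intron_length
    span = 2 * exon + intron
    go_pool = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    gene_no = 0
    for chrom in config.placed_ids:
        length = lengths[chrom]
        n_genes = int(round(config.genes_per_mb * length / 1e6))
        if n_genes == 0:
            continue
        if n_genes * (span + 1) > length:
            raise ValueError(
                f"cannot place {n_genes} genes of span {span} bp on {chrom} "
                f"({length} bp); lower genes_per_mb"
            )
        # place genes in equal slots with random jitter -> guaranteed non-overlap
        slot = length // n_genes
        if slot <= span:
            raise ValueError(f"gene density too high on {chrom}; lower genes_per_mb")
        for k in range(n_genes):
            offset = int(rng.integers(0, slot - span))
            start = k * slot + offset + 1  # 1-based
            strand = "+" if rng.random() < 0.5 else "-"
            n_codons = 2 * exon // 3
            coding = _random_cds_sequence(n_codons, rng)
            ex1 = (start, start + exon - 1)
            ex2 = (start + exon + intron, start + span - 1)
            if strand == "+":
                seq1, seq2 = coding[:exon], coding[exon:]
            else:
                rc = _revcomp(coding)
                seq1, seq2 = rc[:exon], rc[exon:]
            sequences[chrom][ex1[0] - 1:ex1[1]] = seq1.encode()
            sequences[chrom][ex2[0] - 1:ex2[1]] = seq2.encode()
            gene_no += 1
            n_terms = int(rng.poisson(config.go_terms_per_gene_mean)) if go_pool else 0
            terms = frozenset(
                rng.choice(go_pool, size=min(n_terms, len(go_pool)), replace=False)
            ) if n_terms else frozenset()
            gene_models.append(GeneModel(
                gene_id=f"gene{gene_no:05d}", chrom=chrom, strand=strand,
                cds=[ex1, ex2], go_terms=terms,
            ))

    genome = Genome(
        sequences={c: s.decode() for c, s in sequences.items()},
        placed=set(config.placed_ids),
        subgenome={c: ("A" if i < config.n_placed // 2 else "B")
                   for i, c in enumerate(config.placed_ids)},
    )
    return genome, gene_models


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

class _PositionSampler:
    """Draws never-reused 1-based positions, optionally ref-base constrained."""

    def __init__(self, genome: Genome, chroms: list[str], rng: np.random.Generator):
        self.genome = genome
        self.chroms = chroms
        self.lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=np.int64)
        self.total = int(self.lengths.sum())
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, ref_in: str | None = None, max_tries: int = 10_000) -> tuple[str, int, str]:
        for _ in range(max_tries):
            flat = int(self.rng.integers(0, self.total))
            ci = int(np.searchsorted(self.offsets, flat, side="right") - 1)
            chrom = self.chroms[ci]
            pos = int(flat - self.offsets[ci]) + 1
            if (chrom, pos) in self.used:
                continue
            ref = self.genome.base_at(chrom, pos)
            if ref_in is not None and ref not in ref_in:
                continue
            self.used.add((chrom, pos))
            return chrom, pos, ref
        raise ValueError("requested mutation count exceeds available positions")


def _non_ref_bases(ref: str) -> list[str]:
    return [b for b in "ACGT" if b != ref]


def simulate_population(
    genome: Genome,
    gene_models: list[GeneModel],  # noqa: ARG001 - kept for interface symmetry
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[VariantSite], GroundTruth]:
    """Plant background, wild-type-noise and EMS sites; emit joint genotypes.

    All planted positions are pairwise distinct. Background sites carry the
    same homozygous alternate in every sample; WT-noise sites deviate in
    exactly one control; EMS sites are private to one mutant (zygosity
    Bernoulli with the configured homozygous fraction) unless shared or
    scaffold variants are requested. Missing genotypes are injected last.
    """
    wt_ids = config.wildtype_ids
    mutant_ids = config.mutant_ids
    samples = mutant_ids + wt_ids

    placed = [c for c in sorted(genome.placed)]
    all_chroms = sorted(genome.sequences)
    placed_sampler = _PositionSampler(genome, placed, rng)
    unplaced = [c for c in all_chroms if c not in genome.placed]

    # one shared `used` set across samplers keeps the three site classes disjoint
    genome_sampler = _PositionSampler(genome, all_chroms, rng)
    genome_sampler.used = placed_sampler.used
    scaffold_sampler = None
    if unplaced:
        scaffold_sampler = _PositionSampler(genome, unplaced, rng)
        scaffold_sampler.used = placed_sampler.used

    truth = GroundTruth(
        ems_sites={m: [] for m in mutant_ids},
        unplaced_ems_sites={m: [] for m in mutant_ids},
    )
    sites: list[VariantSite] = []

    def emit(chrom: str, pos: int, ref: str, alt: str,
             genotypes: dict[str, GenotypeLike]) -> None:
        sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 genotypes=genotypes))

    hom = Genotype.from_alleles
    total_len = sum(len(s) for s in genome.sequences.values())

    # --- background divergence: hom-alt in all samples --------------------
    n_background = int(round(config.background_rate * total_len))
    for _ in range(n_background):
        chrom, pos, ref = genome_sampler.draw()
        alt = str(rng.choice(_non_ref_bases(ref)))
        gts = {s: hom(alt, alt) for s in samples}
        emit(chrom, pos, ref, alt, gts)
        truth.background_sites.append((chrom, pos, ref, alt))

    # --- individual WT noise: one control deviates ------------------------
    n_noise = int(round(config.wt_noise_rate * total_len))
    for _ in range(n_noise):
        chrom, pos, ref = genome_sampler.draw()
        alt = str(rng.choice(_non_ref_bases(ref)))
        deviant = wt_ids[int(rng.integers(0, len(wt_ids)))]
        gts: dict[str, GenotypeLike] = {s: hom(ref, ref) for s in samples}
        gts[deviant] = hom(alt, alt) if rng.random() < 0.5 else hom(ref, alt)
        emit(chrom, pos, ref, alt, gts)
        truth.wt_noise_sites.append((chrom, pos, ref, alt))

    # --- per-mutant EMS mutations -----------------------------------------
    if config.ems_counts is not None:
        ems_counts = list(config.ems_counts)
    else:
        lo, hi = config.ems_count_range
        ems_counts = [int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                      for _ in mutant_ids]
    probs = config.spectrum_probs()

    def plant_ems(mutant: str, sampler: _PositionSampler, registry) -> None:
        cls = SPECTRUM_CLASSES[int(rng.choice(len(SPECTRUM_CLASSES), p=probs))]
        subs = _CLASS_SUBS[cls]
        chrom, pos, ref = sampler.draw(ref_in="".join(subs))
        alt = subs[ref]
        homozygous = rng.random() < config.homozygous_fraction
        gts: dict[str, GenotypeLike] = {s: hom(ref, ref) for s in samples}
        gts[mutant] = hom(alt, alt) if homozygous else hom(ref, alt)
        emit(chrom, pos, ref, alt, gts)
        registry.append((chrom, pos, ref, alt, "hom" if homozygous else "het"))

    for mutant, count in zip(mutant_ids, ems_counts):
        for _ in range(count):
            plant_ems(mutant, placed_sampler, truth.ems_sites[mutant])
        n_scaffold = int(round(config.scaffold_ems_fraction * count))
        if scaffold_sampler is not None:
            for _ in range(n_scaffold):
                plant_ems(mutant, scaffold_sampler, truth.unplaced_ems_sites[mutant])

    # --- mutant-shared sites (exercise cascade steps 3/5) ------------------
    n_shared = int(round(config.shared_mutant_fraction * float(np.mean(ems_counts))))
    for _ in range(n_shared):
        chrom, pos, ref = placed_sampler.draw()
        alt = str(rng.choice(_non_ref_bases(ref)))
        gts = {s: hom(ref, ref) for s in samples}
        for m in mutant_ids:
            gts[m] = hom(alt, alt)
        emit(chrom, pos, ref, alt, gts)
        truth.shared_mutant_sites.append((chrom, pos, ref, alt))

    # --- missing genotypes --------------------------------------------------
    if config.missing_rate > 0:
        masked: list[VariantSite] = []
        for site in sites:
            gts = dict(site.genotypes)
            for s in samples:
                if rng.random() < config.missing_rate:
                    gts[s] = MISSING
            masked.append(VariantSite(site.chrom, site.pos, site.ref, site.alt, gts))
        sites = masked

    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites, truth


def simulate_study(
    config: SimulationConfig, seed: int
) -> tuple[Genome, list[GeneModel], list[VariantSite], GroundTruth]:
    """Genome, gene models, joint SNP calls and truth for one seeded study."""
    rng = np.random.default_rng(seed)
    genome, gene_models = simulate_genome(config, rng)
    sites, truth = simulate_population(genome, gene_models, config, rng)
    return genome, gene_models, sites, truth


# ---------------------------------------------------------------------------
# on-disk study
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, genome: Genome, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_gff(path: Path, gene_models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            attrs = f"ID={gm.gene_id}"
            fh.write(f"{gm.chrom}\temsift\tgene\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\t{attrs}\n")
            mrna = f"{gm.gene_id}.t1"
            fh.write(f"{gm.chrom}\temsift\tmRNA\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\t"
                     f"ID={mrna};Parent={gm.gene_id}\n")
            for s, e in gm.cds:
                fh.write(f"{gm.chrom}\temsift\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\t"
                         f"ID={mrna}.cds;Parent={mrna}\n")


def write_study(
    out_dir: str | Path,
    config: SimulationConfig,
    seed: int,
) -> dict[str, Path]:
    """Simulate a study and write study.vcf / genome.fa / genes.gff3 /
    gene2go.tsv / truth.json into ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, gene_models, sites, truth = simulate_study(config, seed)

    paths = {
        "vcf": out / "study.vcf",
        "fasta": out / "genome.fa",
        "gff": out / "genes.gff3",
        "gene2go": out / "gene2go.tsv",
        "truth": out / "truth.json",
    }
    samples = config.mutant_ids + config.wildtype_ids
    write_vcf(paths["vcf"], sites, samples, contig_lengths=genome.lengths)
    _write_fasta(paths["fasta"], genome)
    _write_gff(paths["gff"], gene_models)
    write_gene2go(paths["gene2go"], {g.gene_id: g.go_terms for g in gene_models
                                     if g.go_terms})
    paths["truth"].write_text(truth.to_json())
    return paths
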