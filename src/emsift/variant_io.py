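"""Data model and readers/writers for the formats the pipeline touches.

Conventions
-----------
* All coordinates are 1-based inclusive, matching both VCF and GFF3; no
  internal conversion to half-open intervals ever happens.
* A genotype is an unordered pair of nucleotides (phasing is ignored:
  ``0|1`` is the same genotype as ``0/1``) or :data:`MISSING`.
* Multiallelic VCF records are decomposed into one biallelic
  :class:`VariantSite` per alternate allele; a sample genotype that
  references a different alternate becomes :data:`MISSING` at the
  decomposed site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: Default pattern deciding which FASTA records count as placed chromosomes.
PLACED_CHROM_RE = re.compile(r"^[Cc]hr\w*\d+$")


class _Missing:
    """Singleton sentinel for an uncalled genotype ('N', './.' or half-call)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()


@dataclass(frozen=True, order=True)
class Genotype:
    """An unordered diploid genotype, e.g. ``Genotype.from_alleles("T", "C")``.

    Alleles are stored sorted so that (C,T) and (T,C) compare equal, which
    is what the filtering cascade's identity tests require.
    """

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if tuple(sorted(self.alleles)) != self.alleles:
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        for a in self.alleles:
            if a not in NUCLEOTIDES:
                raise ValueError(f"invalid allele {a!r}")

    @classmethod
    def from_alleles(cls, a: str, b: str) -> "Genotype":
        return cls(tuple(sorted((a.upper(), b.upper()))))

    @property
    def is_hom(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def carries(self, allele: str) -> bool:
        return allele in self.alleles

    def __repr__(self) -> str:
        return f"({self.alleles[0]},{self.alleles[1]})"


#: A genotype value is either a :class:`Genotype` or :data:`MISSING`.
GenotypeLike = Genotype | _Missing


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-sample genotypes.

    ``pos`` is 1-based. ``ref`` and ``alt`` are single nucleotides and
    differ. Every sample declared for the study must be present in
    ``genotypes``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, GenotypeLike]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele not in NUCLEOTIDES:
                raise ValueError(f"non-SNP allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample: str) -> GenotypeLike:
        return self.genotypes[sample]


@dataclass
class GeneModel:
    """A protein-coding gene reduced to the transcript with the longest CDS.

    ``cds`` holds 1-based inclusive (start, end) intervals in genomic order
    (ascending), regardless of strand; 5'->3' reading on the minus strand
    walks the list backwards with reverse-complementation.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class Genome:
    """Reference sequences plus the set of placed chromosomes.

    ``subgenome`` labels each placed chromosome "A" or "B" (allotetraploid
    convention) and every other record "unplaced"; only placed chromosomes
    count toward per-chromosome statistics.
    """

    sequences: dict[str, str]
    placed: set[str]
    subgenome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = self.placed - set(self.sequences)
        if unknown:
            raise ValueError(f"placed chromosomes missing from sequences: {sorted(unknown)}")
        for name in self.sequences:
            self.subgenome.setdefault(name, "unplaced" if name not in self.placed else "A")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def placed_lengths_mb(self) -> dict[str, float]:
        return {c: len(self.sequences[c]) / 1e6 for c in sorted(self.placed)}

    def base_at(self, chrom: str, pos: int) -> str:
        """1-based lookup."""
        return self.sequences[chrom][pos - 1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, placed: Iterable[str] | None = None) -> Genome:
    """Load a reference FASTA.

    Parameters
    ----------
    path
        FASTA file (uncompressed).
    placed
        Explicit ids of placed chromosomes. When omitted, records whose id
        matches ``Chr<number>`` are considered placed and everything else an
        unplaced scaffold.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if placed is None:
        placed_set = {name for name in sequences if PLACED_CHROM_RE.match(name)}
    else:
        placed_set = set(placed)
    return Genome(sequences=sequences, placed=placed_set)


def _decode_gt(sample_rec, ref: str, alts: Sequence[str], alt_index: int) -> GenotypeLike:
    """Map one pysam sample record to a Genotype at the decomposed site.

    ``alt_index`` is the 0-based index of the alternate allele this
    decomposed site carries. Any allele index referring to a *different*
    alternate makes the genotype MISSING here, as does any missing allele
    (half-calls included).
    """
    idx = sample_rec.get("GT", (None,))
    if idx is None:
        return MISSING
    alleles: list[str] = []
    for i in idx:
        if i is None:
            return MISSING
        if i == 0:
            alleles.append(ref)
        elif i == alt_index + 1:
            alleles.append(alts[alt_index])
        else:
            return MISSING
    if len(alleles) != 2:
        return MISSING
    return Genotype.from_alleles(*alleles)


def read_vcf(
    path: str | Path,
    sample_roles: Mapping[str, str] | None = None,
) -> tuple[list[VariantSite], int]:
    """Read SNP records from a VCF 4.x file.

    Parameters
    ----------
    path
        VCF path (plain text or bgzipped).
    sample_roles
        Map of sample id -> ``"mutant"`` or ``"wildtype"``. When given,
        every declared sample must be present in the VCF header (a missing
        one raises :class:`ValueError`) and only declared samples are kept
        in the genotype maps.

    Returns
    -------
    (sites, skipped)
        ``sites`` are biallelic :class:`VariantSite` records (multiallelic
        records decomposed per alternate); ``skipped`` counts non-SNP
        records (indels/MNPs/symbolic alleles) that were dropped.
    """
    vf = pysam.VariantFile(str(path))
    header_samples = list(vf.header.samples)
    if sample_roles is not None:
        missing = [s for s in sample_roles if s not in header_samples]
        if missing:
            raise ValueError(
                f"samples declared in roles but absent from VCF: {', '.join(missing)}"
            )
        keep = [s for s in header_samples if s in sample_roles]
    else:
        keep = header_samples

    sites: list[VariantSite] = []
    skipped = 0
    for rec in vf:
        ref = (rec.ref or "").upper()
        alts = tuple((a or "").upper() for a in (rec.alts or ()))
        if len(ref) != 1 or ref not in NUCLEOTIDES or not alts:
            skipped += 1
            continue
        snp_alts = [
            (i, a) for i, a in enumerate(alts) if len(a) == 1 and a in NUCLEOTIDES
        ]
        if not snp_alts:
            skipped += 1
            continue
        for alt_index, alt in snp_alts:
            genotypes: dict[str, GenotypeLike] = {}
            for sample in keep:
                try:
                    genotypes[sample] = _decode_gt(rec.samples[sample], ref, alts, alt_index)
                except (KeyError, ValueError) as exc:  # malformed GT field
                    raise ValueError(
                        f"malformed genotype for sample {sample} at "
                        f"{rec.chrom}:{rec.pos}: {exc}"
                    ) from exc
            sites.append(
                VariantSite(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, genotypes=genotypes)
            )
    if skipped:
        logger.info("read_vcf: skipped %d non-SNP records", skipped)
    return sites, skipped


def write_vcf(
    path: str | Path,
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write sites as an uncompressed, genotype-only VCF 4.2 file.

    Genotypes are emitted unphased; MISSING becomes ``./.``. Sites are
    written in the order given (callers sort beforehand if desired).
    """
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    contigs: dict[str, int | None]
    if contig_lengths is not None:
        contigs = dict(contig_lengths)
    else:
        contigs = {}
        for site in sites:
            contigs.setdefault(site.chrom, None)
    for name, length in contigs.items():
        if length is None:
            header.contigs.add(name)
        else:
            header.contigs.add(name, length=length)
    for sample in samples:
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1, stop=site.pos,
                alleles=(site.ref, site.alt),
            )
            for sample in samples:
                gt = site.genotypes[sample]
                if gt is MISSING:
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    indices = tuple(0 if a == site.ref else 1 for a in gt.alleles)
                    rec.samples[sample]["GT"] = indices
                rec.samples[sample].phased = False
            out.write(rec)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one model per gene (longest-CDS mRNA).

    CDS features without a resolvable parent gene are skipped with a
    warning. Returned CDS intervals are 1-based inclusive in genomic order.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique", sort_attribute_values=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            length = sum(e - s + 1 for s, e in cds)
            if best is None or length > best[0]:
                best = (length, mrna.id, sorted(cds))
        if best is None:
            # genes with CDS directly attached (no mRNA level)
            cds = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
            if cds:
                best = (sum(e - s + 1 for s, e in cds), gene.id, sorted(cds))
        if best is None:
            continue
        models.append(
            GeneModel(gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, cds=best[2])
        )
    # orphan CDS check
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype=("gene", "mRNA")))
        if not parents:
            logger.warning("CDS at %s:%d-%d has no parent gene; skipped",
                           cds.seqid, cds.start, cds.end)
    return models


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of (gene id, GO term id) pairs.

    Duplicate pairs are collapsed; a malformed line raises ValueError with
    its 1-based line number.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed gene2go line {lineno}: {line!r}")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def write_gene2go(path: str | Path, mapping: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")
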