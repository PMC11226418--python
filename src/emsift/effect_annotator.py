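"""Functional classification of attributed SNPs (SnpEff-level categories).

Each SNP is classified against every gene model it touches: CDS hits are
translated (strand-aware) into synonymous / non-synonymous / stop-gain
calls; positions inside the gene span but outside CDS are intronic;
positions within a flanking window (default 5 kb, the usual annotation
convention) are upstream or downstream relative to the gene's strand;
everything else is intergenic. A per-SNP single category is obtained by
severity reduction:

    stop_gain > non_synonymous > synonymous > intron
              > upstream = downstream > intergenic

stop-loss and start-loss changes are folded into non_synonymous; splice
classes and UTRs are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from intervaltree import IntervalTree

from emsift.ems_filter import MutantCall, MutantCallSet
from emsift.variant_io import GeneModel, Genome, VariantSite

__all__ = [
    "CATEGORIES",
    "EffectCall",
    "AnnotatedCall",
    "Annotator",
    "classify_site",
    "annotate_callsets",
    "genes_with_category",
    "reduce_to_primary",
]

CATEGORIES = (
    "stop_gain", "non_synonymous", "synonymous", "intron",
    "upstream", "downstream", "intergenic",
)

_SEVERITY = {
    "stop_gain": 0, "non_synonymous": 1, "synonymous": 2, "intron": 3,
    "upstream": 4, "downstream": 4, "intergenic": 5,
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate(codon: str) -> str:
    """One-letter amino acid, '*' for stop (standard nuclear code)."""
    return "*" if codon in _STOPS else _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class EffectCall:
    """One gene-level effect of one SNP."""

    category: str
    gene_id: str | None = None
    codon_change: str | None = None  # e.g. "CAA>TAA"
    aa_change: str | None = None     # e.g. "Q>*"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def severity(self) -> int:
        return _SEVERITY[self.category]


@dataclass(frozen=True)
class AnnotatedCall:
    """A mutant's SNP call together with its effect annotation."""

    call: MutantCall
    effects: tuple[EffectCall, ...]
    primary: EffectCall


def reduce_to_primary(effects: Sequence[EffectCall]) -> EffectCall:
    """Most severe effect; ties broken by gene id for determinism."""
    if not effects:
        raise ValueError("no effects to reduce")
    return min(effects, key=lambda e: (e.severity, e.gene_id or ""))


class Annotator:
    """Reusable site classifier over one genome + gene-model set.

    Builds per-chromosome interval indexes of gene spans extended by
    ``window_bp`` so repeated classification is cheap, and caches each
    gene's spliced coding sequence for codon lookups.
    """

    def __init__(self, gene_models: Iterable[GeneModel], genome: Genome,
                 window_bp: int = 5_000):
        if window_bp <= 0:
            raise ValueError("window_bp must be positive")
        self.genome = genome
        self.window_bp = window_bp
        self.genes = {g.gene_id: g for g in gene_models}
        self._trees: dict[str, IntervalTree] = {}
        self._coding_cache: dict[str, str] = {}
        for gene in self.genes.values():
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            # interval is half-open; store the window-extended gene span
            tree[max(1, gene.start - window_bp): gene.end + window_bp + 1] = gene.gene_id

    # -- codon machinery ----------------------------------------------------

    def _coding_sequence(self, gene: GeneModel) -> str:
        cached = self._coding_cache.get(gene.gene_id)
        if cached is not None:
            return cached
        chrom_seq = self.genome.sequences[gene.chrom]
        spliced = "".join(chrom_seq[s - 1:e] for s, e in gene.cds)
        if gene.strand == "-":
            spliced = spliced.translate(_COMPLEMENT)[::-1]
        self._coding_cache[gene.gene_id] = spliced
        return spliced

    @staticmethod
    def _coding_offset(gene: GeneModel, pos: int) -> int | None:
        """0-based position within the spliced CDS (5'->3'), or None."""
        forward = 0
        offset = None
        for s, e in gene.cds:
            if s <= pos <= e:
                offset = forward + (pos - s)
            forward += e - s + 1
        if offset is None:
            return None
        return offset if gene.strand == "+" else forward - 1 - offset

    def _coding_call(self, gene: GeneModel, pos: int, alt: str) -> EffectCall | None:
        offset = self._coding_offset(gene, pos)
        if offset is None:
            return None
        coding = self._coding_sequence(gene)
        codon_i, within = divmod(offset, 3)
        ref_codon = coding[3 * codon_i: 3 * codon_i + 3]
        alt_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
        ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
        if alt_aa == "*" and ref_aa != "*":
            category = "stop_gain"
        elif ref_aa == alt_aa:
            category = "synonymous"
        else:
            # includes stop_lost (ref '*'), folded into non_synonymous
            category = "non_synonymous"
        return EffectCall(category=category, gene_id=gene.gene_id,
                          codon_change=f"{ref_codon}>{alt_codon}",
                          aa_change=f"{ref_aa}>{alt_aa}")

    # -- public API ----------------------------------------------------------

    def classify(self, chrom: str, pos: int, alt: str) -> list[EffectCall]:
        if chrom in self.genome.sequences and pos > len(self.genome.sequences[chrom]):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        calls: list[EffectCall] = []
        tree = self._trees.get(chrom)
        for iv in sorted(tree[pos]) if tree is not None else []:
            gene = self.genes[iv.data]
            if gene.start <= pos <= gene.end:
                coding = self._coding_call(gene, pos, alt)
                calls.append(coding if coding is not None
                             else EffectCall(category="intron", gene_id=gene.gene_id))
            elif pos < gene.start:
                side = "upstream" if gene.strand == "+" else "downstream"
                calls.append(EffectCall(category=side, gene_id=gene.gene_id))
            else:
                side = "downstream" if gene.strand == "+" else "upstream"
                calls.append(EffectCall(category=side, gene_id=gene.gene_id))
        if not calls:
            calls.append(EffectCall(category="intergenic"))
        return calls


def classify_site(
    site: VariantSite,
    alt: str,
    gene_models: Iterable[GeneModel],
    genome: Genome,
    window_bp: int = 5_000,
) -> list[EffectCall]:
    """One-shot classification (builds a throwaway :class:`Annotator`)."""
    return Annotator(gene_models, genome, window_bp).classify(site.chrom, site.pos, alt)


def annotate_callsets(
    callsets: Mapping[str, MutantCallSet],
    gene_models: Iterable[GeneModel],
    genome: Genome,
    window_bp: int = 5_000,
) -> dict[str, list[AnnotatedCall]]:
    """Annotate every attributed SNP of every mutant.

    Every call receives at least one :class:`EffectCall` plus its
    severity-reduced primary category.
    """
    annotator = Annotator(gene_models, genome, window_bp)
    out: dict[str, list[AnnotatedCall]] = {}
    for mutant, callset in callsets.items():
        annotated = []
        for call in callset:
            effects = tuple(annotator.classify(call.site.chrom, call.site.pos, call.alt))
            annotated.append(AnnotatedCall(call=call, effects=effects,
                                           primary=reduce_to_primary(effects)))
        out[mutant] = annotated
    return out


def genes_with_category(
    annotated: Mapping[str, Sequence[AnnotatedCall]], category: str
) -> dict[str, set[str]]:
    """Per mutant, the distinct genes hit by at least one call of ``category``."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    out: dict[str, set[str]] = {}
    for mutant, calls in annotated.items():
        genes = {
            eff.gene_id
            for ac in calls
            for eff in ac.effects
            if eff.category == category and eff.gene_id is not None
        }
        out[mutant] = genes
    return out
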