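"""The five-step filtering cascade that isolates EMS-induced SNPs.

Starting from jointly-genotyped SNP calls over wild-type (WT) control
plants and independently mutagenized mutant lines, the cascade removes,
in order:

1. sites where the WT controls disagree (individual differences; a
   MISSING WT genotype also disqualifies the site because the consensus
   cannot be certified),
2. sites where the certified WT consensus differs from the reference
   genome (fixed background divergence between the mutagenized cultivar
   and the reference line; any consensus other than homozygous-reference
   counts as divergence),
3. sites where all mutants share one identical non-reference genotype
   (pre-existing variation, not independent mutation),
4. sites on unplaced scaffolds,
5. sites where no mutant genotype is unique among the mutants.

Surviving sites are then attributed per mutant: a mutant owns a site iff
its genotype is called and differs from the WT consensus. One site may be
attributed to more than one mutant (e.g. one line homozygous and another
heterozygous for the same induced allele).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from emsift.variant_io import MISSING, Genome, Genotype, GenotypeLike, VariantSite

__all__ = [
    "FilterTrace",
    "MutantCall",
    "MutantCallSet",
    "wt_consensus",
    "drop_background",
    "drop_shared_mutant",
    "drop_unplaced",
    "uniqueness_filter",
    "attribute_to_mutants",
    "run_cascade",
]


@dataclass
class FilterTrace:
    """Per-step bookkeeping: (step name, sites in, sites removed, sites out)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_removed: int) -> None:
        n_out = n_in - n_removed
        self.steps.append((name, n_in, n_removed, n_out))

    def check_conservation(self) -> bool:
        return all(n_in - removed == n_out for _, n_in, removed, n_out in self.steps)

    def to_rows(self) -> list[dict]:
        return [
            {"step": s, "sites_in": i, "sites_removed": r, "sites_out": o}
            for s, i, r, o in self.steps
        ]


@dataclass(frozen=True)
class MutantCall:
    """One SNP attributed to one mutant line."""

    site: VariantSite
    zygosity: str  # "hom" | "het"
    alt: str       # the attributed substitution is site.ref -> alt

    def __post_init__(self) -> None:
        if self.zygosity not in {"hom", "het"}:
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")


@dataclass
class MutantCallSet:
    """All EMS-attributed SNPs of one mutant."""

    mutant_id: str
    calls: list[MutantCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def site_keys(self) -> set[tuple[str, int, str, str]]:
        return {c.site.key for c in self.calls}

    def n_homozygous(self) -> int:
        return sum(1 for c in self.calls if c.zygosity == "hom")


# ---------------------------------------------------------------------------
# the five steps
# ---------------------------------------------------------------------------

def wt_consensus(
    sites: Sequence[VariantSite], wt_ids: Sequence[str]
) -> tuple[list[tuple[VariantSite, Genotype]], list[VariantSite]]:
    """Step 1: keep sites where every WT control has the same called genotype.

    Returns (kept with their consensus genotype, removed). A MISSING WT
    genotype removes the site: the background cannot be certified there.
    """
    if not wt_ids:
        raise ValueError("at least one wild-type sample is required")
    kept: list[tuple[VariantSite, Genotype]] = []
    removed: list[VariantSite] = []
    for site in sites:
        gts = [site.genotypes[w] for w in wt_ids]
        first = gts[0]
        if first is MISSING or any(g != first for g in gts[1:]):
            removed.append(site)
        else:
            kept.append((site, first))  # type: ignore[arg-type]
    return kept, removed


def drop_background(
    with_consensus: Sequence[tuple[VariantSite, Genotype]]
) -> tuple[list[tuple[VariantSite, Genotype]], list[VariantSite]]:
    """Step 2: drop sites whose WT consensus is not homozygous reference.

    Such sites reflect fixed divergence between the mutagenized cultivar
    and the reference line (heterozygous consensus included), not induced
    mutation.
    """
    kept: list[tuple[VariantSite, Genotype]] = []
    removed: list[VariantSite] = []
    for site, consensus in with_consensus:
        if consensus.is_hom and consensus.alleles[0] == site.ref:
            kept.append((site, consensus))
        else:
            removed.append(site)
    return kept, removed


def drop_shared_mutant(
    sites: Sequence[VariantSite], mutant_ids: Sequence[str]
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Step 3: drop sites where all mutants carry one identical non-reference genotype.

    All-reference mutant genotypes survive here; such sites die naturally
    at attribution (no mutant differs from the consensus).
    """
    if len(mutant_ids) < 2:
        raise ValueError("at least two mutants are required")
    kept: list[VariantSite] = []
    removed: list[VariantSite] = []
    for site in sites:
        gts = [site.genotypes[m] for m in mutant_ids]
        first = gts[0]
        hom_ref = Genotype.from_alleles(site.ref, site.ref)
        if first is not MISSING and first != hom_ref and all(g == first for g in gts[1:]):
            removed.append(site)
        else:
            kept.append(site)
    return kept, removed


def drop_unplaced(
    sites: Sequence[VariantSite], genome: Genome
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Step 4: keep only sites on placed chromosomes."""
    kept = [s for s in sites if s.chrom in genome.placed]
    removed = [s for s in sites if s.chrom not in genome.placed]
    return kept, removed


def _has_unique_mutant(genotypes: Sequence[GenotypeLike]) -> bool:
    counts = Counter(g for g in genotypes if g is not MISSING)
    return any(counts[g] == 1 for g in counts)


def uniqueness_filter(
    sites: Sequence[VariantSite], mutant_ids: Sequence[str]
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Step 5: keep sites where some mutant's called genotype is unique.

    A mutant is unique at a site iff its genotype is not MISSING and no
    other mutant has the same genotype. Mutations are assumed independent
    per line, so an induced allele should be private.
    """
    kept: list[VariantSite] = []
    removed: list[VariantSite] = []
    for site in sites:
        gts = [site.genotypes[m] for m in mutant_ids]
        (kept if _has_unique_mutant(gts) else removed).append(site)
    return kept, removed


def attribute_to_mutants(
    with_consensus: Sequence[tuple[VariantSite, Genotype]],
    mutant_ids: Sequence[str],
) -> dict[str, MutantCallSet]:
    """Attribute surviving sites to mutants (the per-mutant WT comparison).

    A site belongs to every mutant whose genotype is called and differs
    from the WT consensus; zygosity is "hom" iff both alleles equal the
    site's alternate allele.
    """
    callsets = {m: MutantCallSet(mutant_id=m) for m in mutant_ids}
    for site, consensus in with_consensus:
        for m in mutant_ids:
            gt = site.genotypes[m]
            if gt is MISSING or gt == consensus:
                continue
            zygosity = "hom" if gt.is_hom and gt.alleles[0] == site.alt else "het"
            callsets[m].calls.append(MutantCall(site=site, zygosity=zygosity, alt=site.alt))
    return callsets


def run_cascade(
    sites: Sequence[VariantSite],
    sample_roles: Mapping[str, str],
    genome: Genome,
) -> tuple[dict[str, MutantCallSet], FilterTrace]:
    """Run steps 1-5 plus attribution; returns per-mutant call sets and the trace.

    ``sample_roles`` maps each sample id to ``"wildtype"`` or ``"mutant"``.
    """
    wt_ids = sorted(s for s, r in sample_roles.items() if r == "wildtype")
    mutant_ids = sorted(s for s, r in sample_roles.items() if r == "mutant")
    if not wt_ids or not mutant_ids:
        raise ValueError("sample_roles must declare at least one wildtype and one mutant")

    trace = FilterTrace()

    consistent, removed1 = wt_consensus(sites, wt_ids)
    trace.record("wt_consensus", len(sites), len(removed1))

    non_background, removed2 = drop_background(consistent)
    trace.record("drop_background", len(consistent), len(removed2))

    consensus_by_key = {site.key: cons for site, cons in non_background}
    stage2 = [site for site, _ in non_background]

    stage3, removed3 = drop_shared_mutant(stage2, mutant_ids)
    trace.record("drop_shared_mutant", len(stage2), len(removed3))

    stage4, removed4 = drop_unplaced(stage3, genome)
    trace.record("drop_unplaced", len(stage3), len(removed4))

    stage5, removed5 = uniqueness_filter(stage4, mutant_ids)
    trace.record("uniqueness_filter", len(stage4), len(removed5))

    callsets = attribute_to_mutants(
        [(s, consensus_by_key[s.key]) for s in stage5], mutant_ids
    )
    attributed_sites = set().union(*(cs.site_keys for cs in callsets.values())) if callsets else set()
    trace.record("attribution", len(stage5), len(stage5) - len(attributed_sites))
    return callsets, trace
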