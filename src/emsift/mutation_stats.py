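"""Descriptive statistics of attributed EMS SNPs.

Covers the substitution spectrum (six strand-symmetric classes),
per-chromosome mutation frequencies in SNPs/Mb with Sum/Average/Min/Max
summary rows, zygosity tallies, annotation-class relative abundances, and
per-chromosome counts of genes carrying non-synonymous or stop-gain SNPs.

Frequencies are computed with exact chromosome lengths (bp / 1e6);
rounding to one decimal happens only at presentation. The summary
"Average" over chromosomes is the unweighted mean of the per-chromosome
values (i.e. Sum/18 for an 18-chromosome genome), not total SNPs divided
by total Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from emsift.effect_annotator import CATEGORIES, AnnotatedCall
from emsift.ems_filter import MutantCallSet
from emsift.variant_io import Genome

__all__ = [
    "SPECTRUM_ORDER",
    "SpectrumCounts",
    "ChromosomeStatTable",
    "classify_substitution",
    "spectrum",
    "frequency_table",
    "zygosity_counts",
    "annotation_abundance",
    "gene_category_table",
    "summarize_table",
    "load_printed_table",
]

#: Six substitution classes, transitions first (stacked-bar order).
SPECTRUM_ORDER = ("C/G>T/A", "T/A>C/G", "C/G>A/T", "T/A>A/T", "T/A>G/C", "C/G>G/C")

_PURINES = {"A", "G"}

# canonical (ref, alt) -> class, after strand-symmetric pooling
_SUB_CLASS = {
    ("C", "T"): "C/G>T/A", ("G", "A"): "C/G>T/A",
    ("T", "C"): "T/A>C/G", ("A", "G"): "T/A>C/G",
    ("C", "A"): "C/G>A/T", ("G", "T"): "C/G>A/T",
    ("T", "A"): "T/A>A/T", ("A", "T"): "T/A>A/T",
    ("T", "G"): "T/A>G/C", ("A", "C"): "T/A>G/C",
    ("C", "G"): "C/G>G/C", ("G", "C"): "C/G>G/C",
}


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Return (strand-symmetric class, is_transition) for a substitution."""
    key = (ref.upper(), alt.upper())
    if key not in _SUB_CLASS:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    is_transition = (ref in _PURINES) == (alt in _PURINES)
    return _SUB_CLASS[key], is_transition


@dataclass
class SpectrumCounts:
    """Counts over the six substitution classes for one mutant."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            raise ValueError("spectrum proportions undefined for an empty call set")
        return {c: self.counts[c] / self.total for c in SPECTRUM_ORDER}

    @property
    def transition_proportion(self) -> float:
        if self.total == 0:
            raise ValueError("spectrum proportions undefined for an empty call set")
        return (self.counts["C/G>T/A"] + self.counts["T/A>C/G"]) / self.total


def spectrum(callset: MutantCallSet) -> SpectrumCounts:
    """Substitution-class counts for one mutant's attributed SNPs."""
    counts = {c: 0 for c in SPECTRUM_ORDER}
    for call in callset:
        cls, _ = classify_substitution(call.site.ref, call.alt)
        counts[cls] += 1
    return SpectrumCounts(counts=counts)


@dataclass
class ChromosomeStatTable:
    """Per-chromosome x per-mutant counts and SNPs/Mb frequencies."""

    counts: pd.DataFrame        # chromosomes x mutants, int
    lengths_mb: pd.Series       # exact bp / 1e6 per chromosome
    frequencies: pd.DataFrame   # counts / lengths_mb

    def frequencies_with_summary(self) -> pd.DataFrame:
        return summarize_table(self.frequencies)

    def counts_with_summary(self) -> pd.DataFrame:
        return summarize_table(self.counts)


def frequency_table(
    callsets: Mapping[str, MutantCallSet], genome: Genome
) -> ChromosomeStatTable:
    """SNP counts and frequencies per placed chromosome and mutant."""
    chroms = sorted(genome.placed)
    mutants = sorted(callsets)
    lengths_mb = pd.Series(
        {c: len(genome.sequences[c]) / 1e6 for c in chroms}, name="length_mb"
    )
    counts = pd.DataFrame(0, index=chroms, columns=mutants, dtype=int)
    for mutant, callset in callsets.items():
        for call in callset:
            if call.site.chrom in counts.index:
                counts.loc[call.site.chrom, mutant] += 1
    frequencies = counts.div(lengths_mb, axis=0)
    return ChromosomeStatTable(counts=counts, lengths_mb=lengths_mb,
                               frequencies=frequencies)


def zygosity_counts(annotated: Sequence[AnnotatedCall]) -> tuple[int, int, int, int]:
    """(total, homozygous, non-synonymous, homozygous-and-non-synonymous)."""
    total = len(annotated)
    hom = sum(1 for a in annotated if a.call.zygosity == "hom")
    nonsyn = sum(1 for a in annotated
                 if any(e.category == "non_synonymous" for e in a.effects))
    both = sum(1 for a in annotated
               if a.call.zygosity == "hom"
               and any(e.category == "non_synonymous" for e in a.effects))
    return total, hom, nonsyn, both


def annotation_abundance(
    annotated: Mapping[str, Sequence[AnnotatedCall]]
) -> pd.DataFrame:
    """Relative abundance of the seven categories per mutant (rows sum to 1).

    Uses the severity-reduced primary category of each SNP, so each SNP
    contributes exactly once.
    """
    rows = {}
    for mutant, calls in annotated.items():
        if not calls:
            raise ValueError(f"no annotated calls for {mutant}; abundance undefined")
        counts = {c: 0 for c in CATEGORIES}
        for a in calls:
            counts[a.primary.category] += 1
        total = len(calls)
        rows[mutant] = {c: counts[c] / total for c in CATEGORIES}
    return pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows)]


def gene_category_table(
    annotated: Mapping[str, Sequence[AnnotatedCall]],
    genome: Genome,
    category: str,
) -> pd.DataFrame:
    """Distinct genes with a ``category`` SNP, per chromosome per mutant.

    A gene is counted once per mutant however many qualifying SNPs hit it
    (the gene-level table convention for non-synonymous / stop-gain
    summaries).
    """
    chroms = sorted(genome.placed)
    mutants = sorted(annotated)
    table = pd.DataFrame(0, index=chroms, columns=mutants, dtype=int)
    for mutant, calls in annotated.items():
        per_chrom: dict[str, set[str]] = {}
        for a in calls:
            for eff in a.effects:
                if eff.category == category and eff.gene_id is not None:
                    per_chrom.setdefault(a.call.site.chrom, set()).add(eff.gene_id)
        for chrom, genes in per_chrom.items():
            if chrom in table.index:
                table.loc[chrom, mutant] = len(genes)
    return table


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append Sum / Average / Min / Max rows (per column) to a chromosome table.

    Arithmetic is exact on the provided values; round only for display.
    """
    body = table.astype(float)
    summary = pd.DataFrame(
        {
            "Sum": body.sum(axis=0),
            "Average": body.mean(axis=0),
            "Min": body.min(axis=0),
            "Max": body.max(axis=0),
        }
    ).T
    return pd.concat([body, summary])


def load_printed_table(which: int) -> pd.DataFrame:
    """Load the packaged fixture of printed per-chromosome values (1, 2 or 3).

    Table 1 holds SNPs/Mb frequencies; Tables 2 and 3 hold counts of genes
    with non-synonymous and stop-gain SNPs respectively. Rows are the 18
    placed chromosomes (printed row order preserved), columns the nine
    mutants R2..R10.
    """
    if which not in (1, 2, 3):
        raise ValueError("which must be 1, 2 or 3")
    ref = resources.files("emsift").joinpath(f"data/table{which}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)
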