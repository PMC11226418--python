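"""End-to-end orchestration: simulate/load -> filter -> annotate -> stats
-> scaling -> enrichment, with plain-text TSV/JSON outputs throughout."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import emsift
from emsift.effect_annotator import annotate_callsets, genes_with_category
from emsift.ems_filter import MutantCallSet, run_cascade
from emsift.genome_scaling import build_dendrogram, entanglement, fit_count_vs_length, untangle
from emsift.go_enrichment import enrich
from emsift.mutation_stats import (
    annotation_abundance,
    frequency_table,
    gene_category_table,
    spectrum,
    zygosity_counts,
)
from emsift.synthetic_data import GroundTruth, SimulationConfig, simulate_study
from emsift.variant_io import (
    Genome,
    read_fasta,
    read_gene2go,
    read_gff,
    read_vcf,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "score_recovery"]


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either ``simulate`` is set (a full synthetic study is generated with
    ``seed``) or the four input paths must point to existing files.
    """

    out_dir: str | Path = "emsift_out"
    vcf: str | Path | None = None
    fasta: str | Path | None = None
    gff: str | Path | None = None
    gene2go: str | Path | None = None
    sample_roles: dict[str, str] | None = None
    truth: str | Path | None = None
    simulate: SimulationConfig | None = None
    seed: int = 0
    window_bp: int = 5_000
    min_term_size: int = 3
    enrichment_alpha: float = 0.05
    entanglement_L: float = 1.5

    def validate(self) -> None:
        if self.simulate is None:
            missing = [name for name in ("vcf", "fasta") if getattr(self, name) is None]
            if missing:
                raise ValueError(f"missing required inputs: {', '.join(missing)}")
            for name in ("vcf", "fasta", "gff", "gene2go", "truth"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {p}")
            if self.sample_roles is None:
                raise ValueError("sample_roles required when not simulating")
            roles = set(self.sample_roles.values())
            if not {"mutant", "wildtype"} <= roles:
                raise ValueError("sample_roles must include mutants and wildtypes")


def score_recovery(
    callsets: Mapping[str, MutantCallSet], truth: GroundTruth
) -> dict[str, dict[str, float]]:
    """Per-mutant precision/recall of recovered sites against planted truth."""
    out: dict[str, dict[str, float]] = {}
    for mutant, callset in callsets.items():
        predicted = callset.site_keys
        expected = truth.ems_keys(mutant)
        tp = len(predicted & expected)
        out[mutant] = {
            "n_predicted": len(predicted),
            "n_true": len(expected),
            "precision": tp / len(predicted) if predicted else float("nan"),
            "recall": tp / len(expected) if expected else float("nan"),
        }
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _write_tsv(path: Path, df: pd.DataFrame, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "emsift",
        "version": emsift.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": [],
    }

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        genome, gene_models, sites, truth = simulate_study(config.simulate, config.seed)
        roles = config.simulate.sample_roles
        gene2go = {g.gene_id: set(g.go_terms) for g in gene_models if g.go_terms}
        skipped = 0
    else:
        genome = read_fasta(config.fasta)
        roles = dict(config.sample_roles or {})
        sites, skipped = read_vcf(config.vcf, roles)
        gene_models = read_gff(config.gff) if config.gff else []
        gene2go = read_gene2go(config.gene2go) if config.gene2go else {}
        if config.truth:
            truth = GroundTruth.from_json(Path(config.truth).read_text())
    manifest["n_input_sites"] = len(sites)
    manifest["n_skipped_records"] = skipped
    manifest["samples"] = roles
    manifest["stages"].append("inputs")

    # ---- filtering cascade ----------------------------------------------
    callsets, trace = _stage("filter")(run_cascade)(sites, roles, genome)
    trace_df = pd.DataFrame(trace.to_rows())
    _write_tsv(out / "filter_trace.tsv", trace_df.set_index("step"))
    mutants = sorted(callsets)
    for mutant in mutants:
        mutant_sites = sorted((c.site for c in callsets[mutant]),
                              key=lambda s: (s.chrom, s.pos))
        write_vcf(out / f"snps_{mutant}.vcf", mutant_sites,
                  samples=sorted(roles), contig_lengths=genome.lengths)
    manifest["per_mutant_snps"] = {m: len(callsets[m]) for m in mutants}
    manifest["stages"].append("filter")

    if truth is not None:
        manifest["recovery"] = score_recovery(callsets, truth)

    # ---- annotation ------------------------------------------------------
    annotated = _stage("annotate")(annotate_callsets)(
        callsets, gene_models, genome, config.window_bp
    )
    for mutant in mutants:
        rows = [{
            "chrom": a.call.site.chrom, "pos": a.call.site.pos,
            "ref": a.call.site.ref, "alt": a.call.alt,
            "zygosity": a.call.zygosity, "category": a.primary.category,
            "gene": a.primary.gene_id or ".",
            "codon_change": a.primary.codon_change or ".",
            "aa_change": a.primary.aa_change or ".",
        } for a in annotated[mutant]]
        if rows:
            pd.DataFrame(rows).sort_values(["chrom", "pos"]).to_csv(
                out / f"effects_{mutant}.tsv", sep="\t", index=False)
    manifest["stages"].append("annotate")

    # ---- statistics ------------------------------------------------------
    stats = frequency_table(callsets, genome)
    _write_tsv(out / "chromosome_counts.tsv", stats.counts_with_summary())
    _write_tsv(out / "chromosome_frequency.tsv",
               stats.frequencies_with_summary(), float_format="%.1f")

    spectra = {m: spectrum(callsets[m]) for m in mutants if len(callsets[m])}
    spec_df = pd.DataFrame({m: s.counts for m, s in spectra.items()})
    _write_tsv(out / "spectrum_counts.tsv", spec_df)
    prop_df = pd.DataFrame({m: s.proportions() for m, s in spectra.items()})
    _write_tsv(out / "spectrum_proportions.tsv", prop_df, float_format="%.4f")

    nonempty = {m: a for m, a in annotated.items() if a}
    if nonempty:
        _write_tsv(out / "annotation_abundance.tsv",
                   annotation_abundance(nonempty), float_format="%.4f")
    zyg = pd.DataFrame(
        {m: dict(zip(("total", "homozygous", "non_synonymous", "hom_non_synonymous"),
                     zygosity_counts(annotated[m]))) for m in mutants}
    )
    _write_tsv(out / "zygosity_counts.tsv", zyg)

    nonsyn_table = gene_category_table(annotated, genome, "non_synonymous")
    stop_table = gene_category_table(annotated, genome, "stop_gain")
    _write_tsv(out / "genes_non_synonymous.tsv", nonsyn_table)
    _write_tsv(out / "genes_stop_gain.tsv", stop_table)
    manifest["stages"].append("stats")

    # ---- scaling ---------------------------------------------------------
    lengths_mb = genome.placed_lengths_mb()
    fits = []
    for mutant in mutants:
        for what, table in (("total", stats.counts),
                            ("non_synonymous", nonsyn_table),
                            ("stop_gain", stop_table)):
            counts = table[mutant].to_dict()
            try:
                fit = fit_count_vs_length(counts, lengths_mb)
            except ValueError as exc:
                logger.warning("scaling skipped for %s/%s: %s", mutant, what, exc)
                continue
            fits.append({"mutant": mutant, "response": what, "slope": fit.slope,
                         "intercept": fit.intercept, "r_squared": fit.r_squared,
                         "p_value": fit.p_value, "n": fit.n})
    if fits:
        _write_tsv(out / "regressions.tsv",
                   pd.DataFrame(fits).set_index(["mutant", "response"]))

    length_dendro = build_dendrogram(lengths_mb)
    (out / "dendrogram_length.nwk").write_text(length_dendro.to_newick() + "\n")
    ent_rows = []
    for mutant in mutants:
        counts = stats.counts[mutant].to_dict()
        if len(set(counts.values())) < 2:
            continue
        count_dendro = build_dendrogram({c: float(v) for c, v in counts.items()})
        (out / f"dendrogram_counts_{mutant}.nwk").write_text(
            count_dendro.to_newick() + "\n")
        raw = entanglement(length_dendro, count_dendro, config.entanglement_L)
        _, _, untangled = untangle(length_dendro, count_dendro, config.entanglement_L)
        ent_rows.append({"mutant": mutant, "entanglement_raw": raw.value,
                         "entanglement_untangled": untangled.value})
    if ent_rows:
        _write_tsv(out / "entanglement.tsv",
                   pd.DataFrame(ent_rows).set_index("mutant"), float_format="%.4f")
    manifest["stages"].append("scaling")

    # ---- GO enrichment ---------------------------------------------------
    if gene2go:
        for category, label in (("non_synonymous", "nonsyn"), ("stop_gain", "stopgain")):
            gene_sets = genes_with_category(annotated, category)
            for mutant in mutants:
                rows = enrich(gene_sets[mutant], gene2go,
                              min_term_size=config.min_term_size,
                              alpha=config.enrichment_alpha)
                if not rows:
                    continue
                df = pd.DataFrame([r.__dict__ for r in rows]).set_index("term")
                _write_tsv(out / f"go_{label}_{mutant}.tsv", df)
        manifest["stages"].append("enrich")
    else:
        logger.info("no gene->GO annotation provided; enrichment skipped")
        manifest["stages"].append("enrich:skipped")

    manifest["filter_trace"] = trace.to_rows()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
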