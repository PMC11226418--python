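# Methods

## Data model and conventions

All coordinates are 1-based inclusive, matching VCF and GFF3. A
genotype is an unordered allele pair — phasing is ignored, so `0|1` and
`1/0` are the same genotype — or MISSING (`./.`, half-calls, and `N`
genotypes all map to MISSING). Multiallelic records are decomposed into
one biallelic site per alternate allele; a genotype referencing a
different alternate becomes MISSING at the decomposed site. These
conventions make the cascade's genotype-identity tests well defined;
they are choices, since joint callers do not prescribe how downstream
set logic should treat half-calls or extra alternates. Indels and MNPs
are skipped on input with a logged count: the analysis is defined for
SNPs only.

## The filtering cascade

The cascade certifies a wild-type background and strips everything that
cannot be an independent induced mutation. Two readings of the early
steps are possible ("certify a consensus, then drop divergence" vs
"collect the WT-shared set and subtract"); they agree on clean
genotypes and differ only under missingness. This implementation takes
the conservative reading:

* **Step 1** requires all WT genotypes identical *and called*. A
  MISSING control removes the site, because the background cannot be
  certified there.
* **Step 2** removes any site whose consensus is not
  homozygous-reference. A heterozygous consensus is cultivar-vs-
  reference divergence (or systematic mis-genotyping), not an induced
  mutation — the mutagenized cultivar is not the reference line.
* **Step 3** removes sites where all mutants share one identical
  *non-reference* genotype. All-reference mutant genotypes survive and
  vanish naturally at attribution (no mutant differs from consensus),
  which avoids silently deleting WT-only variation before it is
  accounted.
* **Step 5** keeps a site iff some mutant's called genotype is unique
  among the mutants (MISSING genotypes are not candidates for
  uniqueness but do not disqualify others).
* **Attribution** assigns a surviving site to every mutant whose called
  genotype differs from the consensus; zygosity is homozygous iff both
  alleles equal the site's alternate. One site can be attributed to
  more than one mutant (one line homozygous, another heterozygous for
  the same allele).

Steps 3–5 are per-site predicates, so they commute; the trace records
the fixed execution order 1→5 and conservation (|in| = |removed| +
|out|) holds at every step by construction and is asserted in tests.

## Effect classification

Each attributed SNP is classified against every gene model whose
window-extended span covers it: CDS positions are translated through
the standard nuclear code with strand-aware complementation
(stop-gain / non-synonymous / synonymous; stop-loss and start-loss are
folded into non-synonymous since they change the protein product and
are vanishingly rare at these scales); in-gene non-CDS positions are
intronic; flanking positions within the window are upstream or
downstream relative to strand. The window defaults to 5,000 bp, the
convention of standard annotators; it is configurable. UTRs and splice
classes are not modelled. For single-category summaries each SNP is
reduced to its most severe call:

    stop_gain > non_synonymous > synonymous > intron
              > upstream = downstream > intergenic

with ties broken by gene id for determinism. Gene-level tables count a
gene once per mutant regardless of how many qualifying SNPs hit it.

## Descriptive statistics

Substitutions are pooled strand-symmetrically (G→A counts with C→T)
into six classes, transitions first. Spectrum proportions are
undefined (an error) for an empty call set rather than silently zero.
Per-chromosome frequencies are count / (length in bp / 1e6), with
rounding to one decimal only at presentation. Summary rows append Sum,
Average, Min, Max per mutant; "Average" is the unweighted mean over
chromosomes (Sum/18), not total SNPs over total Mb — the convention
that makes the packaged printed tables internally consistent. The
packaged fixtures `data/table{1,2,3}.tsv` carry the printed
per-chromosome values (18 chromosomes × 9 mutants) used by the
replication tests; note that printed averages ending in .x5 reflect
round-half-down behaviour of the originating software, so replication
of averages is asserted at printed precision (±0.05) rather than by
re-rounding.

## Scaling models and tanglegrams

Counts are regressed on chromosome length (Mb) by OLS; R² and the
two-sided slope-t p-value (n−2 df) are reported per mutant and
response (total, non-synonymous, stop-gain). A constant response is
reported as slope 0, R² 0, p 1 by convention. Chromosome dendrograms
use absolute differences of the scalar (length or count) with average
linkage; labels are sorted before clustering so ties break
deterministically. Entanglement between two dendrograms over the same
labels is Σ|rank₁−rank₂|^L normalized by the exactly-reversed ordering,
L = 1.5 (the common tanglegram default); 0 means identical leaf
orders, 1 exactly reversed. Because the raw leaf order of a linkage is
an arbitrary child-orientation convention, entanglement is reported
both raw and after greedy subtree-rotation untangling (flips kept only
when they strictly decrease the score; idempotent at its fixed point);
the untangled value is the one to read, and is the value used for the
co-monotonicity invariant in the tests. Exact minimal untangling is
combinatorial and out of scope. Which linkage/distance the original
analyses of real data used is not recoverable, so real-data
entanglement values are not bit-reproducible; the package documents
its configuration instead.

## GO over-representation

The universe is every gene with at least one annotation in the
provided gene→GO table (the conventional ORA default); selected genes
without annotation are dropped from n with a logged count. The raw
p-value is the upper hypergeometric tail computed by summing
log-binomial terms with log-sum-exp; adjustment is Benjamini–Hochberg
step-up with monotonicity enforcement. Defaults: minimum term size 3,
significance at adjusted p < 0.05; raw p-values are also emitted since
reported significance conventions vary. GO-DAG propagation (true-path
annotation) is deliberately not performed.

Because the hypergeometric test is discrete, its achieved type-I level
at α = 0.05 is the largest attainable value ≤ 0.05, which at
desk-scale universes (N ≈ 1000, terms of 50–160 genes, selections of
100) sits around 0.03–0.05. The type-I test therefore compares the
Monte-Carlo rejection rate against the *exact* discrete expectation
computed from the null pmf, and additionally bounds it by the nominal
level plus Monte-Carlo error.

## The simulator

The generator emulates the structure the cascade assumes, at desk
scale (defaults: 18 placed chromosomes of 1 Mb, two 50 kb scaffolds,
5 WT, 9 mutants):

* **background divergence** (default 5×10⁻⁴/bp) planted homozygous-
  alternate in every sample — the fixed cultivar-vs-reference
  differences steps 1–2 remove;
* **WT individual noise** (5×10⁻⁵/bp): exactly one control deviates;
* **per-mutant EMS mutations**, strictly private by default, counts
  drawn log-uniform in 500–5,000 per line to mimic the
  order-of-magnitude spread real mutant libraries show; substitution
  class drawn from a spectrum with transition fraction 0.6 of which
  3/4 are C/G→T/A (the EMS signature); zygosity Bernoulli with
  homozygous fraction 1/3 (an M2 selfing generation fixes roughly a
  third of detectable induced alleles);
* **scaffold mutations** (2% of each line's count) planted on unplaced
  scaffolds and book-kept separately — they exercise step 4 and are
  excluded from recoverable truth;
* options for mutant-shared sites (exercising steps 3/5) and missing
  genotypes (default 0).

Gene models are two-exon ORFs (ATG + sense codons + one stop) spliced
into the uniform-random sequence, so effect classification has exact
expectations and no CDS contains a premature stop. GO terms are
attached per gene from a Poisson(2) number of draws over a 50-term
pool.

What the simulator does *not* emulate: read-level error, coverage
variation, linked inheritance, selection, real genome composition
(GC content, repeats, gene structure) or hotspot clustering. Passing
recovery tests therefore demonstrates the correctness of the set logic
and bookkeeping under the stated genotype model, not robustness to
genotyping error in real data — on real data the missingness and
WT-heterogeneity filters do substantive work, and recovery cannot be
perfect.

## Problem sizes and determinism

Default test and acceptance runs use the 18 Mb desk-scale study
(~20–25k sites), chosen so a complete run takes seconds while leaving
every per-chromosome statistic well populated; the cascade itself is
linear in sites and runs unchanged at genome scale. All randomness
flows through `numpy.random.default_rng` seeded from a single integer;
repeated runs are byte-identical, and the pipeline manifest records
seed and versions.
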