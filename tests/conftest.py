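import numpy as np
import pytest
from hypothesis import settings

from emsift.synthetic_data import SimulationConfig, simulate_study
from emsift.variant_io import MISSING, Genome, Genotype, VariantSite

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

MUTANTS = [f"R{i}" for i in range(2, 11)]
WILDTYPES = [f"R{i}" for i in range(11, 16)]
ROLES = {**{m: "mutant" for m in MUTANTS}, **{w: "wildtype" for w in WILDTYPES}}


def make_site(chrom="Chr01", pos=100, ref="C", alt="T", **genotypes):
    """Build a 14-sample site; unspecified samples are homozygous reference.

    Genotype values: "ref", "hom" (alt/alt), "het" (ref/alt), "miss", or an
    explicit 2-tuple of alleles.
    """
    gts = {}
    for sample in MUTANTS + WILDTYPES:
        spec = genotypes.get(sample, "ref")
        if spec == "ref":
            gts[sample] = Genotype.from_alleles(ref, ref)
        elif spec == "hom":
            gts[sample] = Genotype.from_alleles(alt, alt)
        elif spec == "het":
            gts[sample] = Genotype.from_alleles(ref, alt)
        elif spec == "miss":
            gts[sample] = MISSING
        else:
            gts[sample] = Genotype.from_alleles(*spec)
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=gts)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(11)
    seqs = {
        "Chr01": "".join(rng.choice(list("ACGT"), size=10_000)),
        "Chr02": "".join(rng.choice(list("ACGT"), size=8_000)),
        "scaffold_1": "".join(rng.choice(list("ACGT"), size=2_000)),
    }
    return Genome(sequences=seqs, placed={"Chr01", "Chr02"})


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    config = SimulationConfig(
        n_placed=6,
        placed_lengths=(80_000, 100_000, 120_000, 140_000, 160_000, 180_000),
        n_unplaced=1,
        unplaced_length=20_000,
        ems_count_range=(50, 400),
        genes_per_mb=40,
    )
    genome, gene_models, sites, truth = simulate_study(config, seed=202)
    return config, genome, gene_models, sites, truth
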