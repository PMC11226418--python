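"""The five-step cascade: per-rule behaviour, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import MUTANTS, ROLES, WILDTYPES, make_site
from oracles import naive_site_decision, random_pattern_sites

from emsift.ems_filter import (
    attribute_to_mutants,
    drop_background,
    drop_shared_mutant,
    drop_unplaced,
    run_cascade,
    uniqueness_filter,
    wt_consensus,
)
from emsift.variant_io import Genome, Genotype

GT = Genotype.from_alleles


@pytest.fixture(scope="module")
def two_chrom_genome():
    return Genome(sequences={"Chr01": "A" * 1000, "Chr02": "A" * 1000,
                             "scaffold_1": "A" * 100},
                  placed={"Chr01", "Chr02"})


class TestWtConsensus:
    def test_identical_wts_certified(self):
        site = make_site()  # all WTs hom-ref (C,C)
        kept, removed = wt_consensus([site], WILDTYPES)
        assert removed == [] and kept[0][1] == GT("C", "C")

    def test_individual_difference_removed(self):
        site = make_site(R11="het")  # four (C,C), one (C,T)
        kept, removed = wt_consensus([site], WILDTYPES)
        assert kept == [] and removed == [site]

    def test_missing_wt_removed(self):
        site = make_site(R11="miss")
        kept, removed = wt_consensus([site], WILDTYPES)
        assert kept == [] and removed == [site]

    def test_empty_wt_set_rejected(self):
        with pytest.raises(ValueError):
            wt_consensus([make_site()], [])


class TestDropBackground:
    @pytest.mark.parametrize(
        "consensus, kept_expected",
        [(("C", "C"), True),   # hom-ref: kept
         (("T", "T"), False),  # fixed divergence: removed
         (("C", "T"), False)], # het consensus counts as divergence
    )
    def test_consensus_vs_reference(self, consensus, kept_expected):
        site = make_site(ref="C", alt="T")
        kept, removed = drop_background([(site, GT(*consensus))])
        assert bool(kept) is kept_expected


class TestDropSharedMutant:
    def test_all_mutants_identical_nonref_removed(self):
        site = make_site(**{m: "hom" for m in MUTANTS})
        kept, removed = drop_shared_mutant([site], MUTANTS)
        assert kept == []

    def test_one_differing_mutant_kept(self):
        site = make_site(**{m: "hom" for m in MUTANTS[:-1]})
        kept, _ = drop_shared_mutant([site], MUTANTS)
        assert kept == [site]

    def test_all_reference_kept_for_later(self):
        site = make_site()
        kept, _ = drop_shared_mutant([site], MUTANTS)
        assert kept == [site]


def test_drop_unplaced(two_chrom_genome):
    on_chrom = make_site(chrom="Chr02")
    on_scaffold = make_site(chrom="scaffold_123")
    kept, removed = drop_unplaced([on_chrom, on_scaffold], two_chrom_genome)
    assert kept == [on_chrom] and removed == [on_scaffold]
    kept, removed = drop_unplaced([on_chrom], two_chrom_genome)
    assert removed == []


class TestUniquenessFilter:
    def test_single_unique_mutant_kept(self):
        # R2=(A,A), R3..R10=(C,C)
        site = make_site(ref="C", alt="A", R2="hom")
        kept, _ = uniqueness_filter([site], MUTANTS)
        assert kept == [site]

    def test_two_unique_mutants_kept(self):
        # R2=(A,A), R3=(A,C), rest (C,C)
        site = make_site(ref="C", alt="A", R2="hom", R3="het")
        kept, _ = uniqueness_filter([site], MUTANTS)
        assert kept == [site]

    def test_five_vs_four_split_removed(self):
        pattern = {m: "hom" for m in MUTANTS[:5]}
        pattern.update({m: "het" for m in MUTANTS[5:]})
        site = make_site(**pattern)
        kept, removed = uniqueness_filter([site], MUTANTS)
        assert kept == [] and removed == [site]


class TestAttribution:
    def test_hom_het_and_missing(self):
        site = make_site(ref="C", alt="T", R2="hom", R3="het", R4="miss")
        callsets = attribute_to_mutants([(site, GT("C", "C"))], MUTANTS)
        assert [(c.zygosity, c.alt) for c in callsets["R2"]] == [("hom", "T")]
        assert [(c.zygosity, c.alt) for c in callsets["R3"]] == [("het", "T")]
        assert len(callsets["R4"]) == 0

    def test_multi_attribution_single_site(self):
        site = make_site(ref="C", alt="A", R2="hom", R3="het")
        callsets = attribute_to_mutants([(site, GT("C", "C"))], MUTANTS)
        attributed = {m for m in MUTANTS if len(callsets[m])}
        assert attributed == {"R2", "R3"}


class TestRunCascade:
    def test_background_only_study_yields_empty_callsets(self, two_chrom_genome):
        sites = [make_site(pos=i + 1, **{s: "hom" for s in MUTANTS + WILDTYPES})
                 for i in range(20)]
        callsets, trace = run_cascade(sites, ROLES, two_chrom_genome)
        assert all(len(cs) == 0 for cs in callsets.values())
        assert trace.steps[1][2] == 20  # all removed as background

    def test_hand_fixture_matches_oracle(self, two_chrom_genome):
        rng = np.random.default_rng(17)
        sites = random_pattern_sites(rng, 20, WILDTYPES, MUTANTS,
                                     ["Chr01", "Chr02"], ["scaffold_1"])
        self._assert_oracle_equivalence(sites, two_chrom_genome)

    def _assert_oracle_equivalence(self, sites, genome):
        callsets, trace = run_cascade(sites, ROLES, genome)
        assert trace.check_conservation()
        expected = {m: set() for m in MUTANTS}
        for site in sites:
            decision = naive_site_decision(site, WILDTYPES, MUTANTS, genome.placed)
            if decision:
                for m in decision:
                    expected[m].add(site.key)
        for m in MUTANTS:
            assert callsets[m].site_keys == expected[m]

    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_on_random_patterns(self, seed, two_chrom_genome):
        rng = np.random.default_rng(seed)
        sites = random_pattern_sites(rng, 60, WILDTYPES, MUTANTS,
                                     ["Chr01", "Chr02"], ["scaffold_1"])
        self._assert_oracle_equivalence(sites, two_chrom_genome)

    @given(seed=st.integers(0, 10_000))
    def test_steps_3_4_5_commute(self, seed, two_chrom_genome):
        """Set-intersection semantics: later steps commute pairwise."""
        rng = np.random.default_rng(seed)
        sites = random_pattern_sites(rng, 40, WILDTYPES, MUTANTS,
                                     ["Chr01", "Chr02"], ["scaffold_1"])
        ops = {
            "shared": lambda ss: drop_shared_mutant(ss, MUTANTS)[0],
            "unplaced": lambda ss: drop_unplaced(ss, two_chrom_genome)[0],
            "unique": lambda ss: uniqueness_filter(ss, MUTANTS)[0],
        }
        baseline = None
        import itertools
        for perm in itertools.permutations(ops.values()):
            out = list(sites)
            for op in perm:
                out = op(out)
            keys = {s.key for s in out}
            baseline = keys if baseline is None else baseline
            assert keys == baseline

    @given(seed=st.integers(0, 10_000))
    def test_adding_concordant_wt_never_changes_output(self, seed, two_chrom_genome):
        rng = np.random.default_rng(seed)
        sites = random_pattern_sites(rng, 40, WILDTYPES, MUTANTS,
                                     ["Chr01", "Chr02"], ["scaffold_1"])
        callsets, _ = run_cascade(sites, ROLES, two_chrom_genome)

        augmented = []
        for site in sites:
            gts = dict(site.genotypes)
            gts["R99"] = gts[WILDTYPES[0]]  # always matches an existing WT
            augmented.append(type(site)(site.chrom, site.pos, site.ref, site.alt, gts))
        roles2 = {**ROLES, "R99": "wildtype"}
        callsets2, _ = run_cascade(augmented, roles2, two_chrom_genome)
        # sites whose WTs already agreed keep their attribution unchanged
        for m in MUTANTS:
            assert callsets[m].site_keys == callsets2[m].site_keys

    def test_simulated_truth_recovered_exactly(self, small_study):
        config, genome, _, sites, truth = small_study
        callsets, trace = run_cascade(sites, config.sample_roles, genome)
        assert trace.check_conservation()
        for mutant in config.mutant_ids:
            assert callsets[mutant].site_keys == truth.ems_keys(mutant)
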