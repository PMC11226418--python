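"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-state the filtering rules per site in the plainest
possible form, sharing no code with the cascade implementation.
"""

from collections import Counter

import numpy as np

from emsift.variant_io import MISSING, Genotype, VariantSite


def naive_site_decision(site, wt_ids, mutant_ids, placed):
    """Evaluate all cascade rules on one site.

    Returns the set of mutants the site is attributed to, or None if any
    rule removes the site (empty set = survives but unattributed).
    """
    wt = [site.genotypes[w] for w in wt_ids]
    if any(g is MISSING for g in wt):
        return None
    if any(g != wt[0] for g in wt):
        return None
    consensus = wt[0]
    hom_ref = Genotype.from_alleles(site.ref, site.ref)
    if consensus != hom_ref:
        return None
    mut = [site.genotypes[m] for m in mutant_ids]
    if all(g is not MISSING for g in mut) and len(set(mut)) == 1 and mut[0] != hom_ref:
        return None
    if site.chrom not in placed:
        return None
    counts = Counter(g for g in mut if g is not MISSING)
    if not any(c == 1 for c in counts.values()):
        return None
    return {
        m for m in mutant_ids
        if site.genotypes[m] is not MISSING and site.genotypes[m] != consensus
    }


def random_pattern_sites(rng, n_sites, wt_ids, mutant_ids, placed, unplaced):
    """Random genotype-pattern sites exercising every removal reason."""
    samples = list(mutant_ids) + list(wt_ids)
    chroms = list(placed) + list(unplaced)
    sites = []
    for i in range(n_sites):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        pool = [
            Genotype.from_alleles(ref, ref),
            Genotype.from_alleles(ref, alt),
            Genotype.from_alleles(alt, alt),
            MISSING,
        ]
        # mixture of structured and fully random patterns
        kind = rng.integers(0, 4)
        gts = {}
        if kind == 0:        # fully random
            for s in samples:
                gts[s] = pool[rng.integers(0, 4)]
        elif kind == 1:      # clean consensus, random mutants
            for s in wt_ids:
                gts[s] = pool[0]
            for m in mutant_ids:
                gts[m] = pool[rng.integers(0, 4)]
        elif kind == 2:      # background-like: all identical non-ref
            g = pool[rng.integers(1, 3)]
            for s in samples:
                gts[s] = g
        else:                # mutant-shared
            for s in wt_ids:
                gts[s] = pool[0]
            g = pool[rng.integers(1, 3)]
            for m in mutant_ids:
                gts[m] = g
        chrom = chroms[rng.integers(0, len(chroms))]
        sites.append(VariantSite(chrom=chrom, pos=i + 1, ref=str(ref), alt=str(alt),
                                 genotypes=gts))
    return sites


def ols_normal_equations(x, y):
    """Closed-form simple linear regression: slope, intercept, r2, p."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res == 0:
        p = 0.0
    else:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


def naive_agglomerate(values):
    """O(n^3) average-linkage clustering on |difference| of scalars.

    Merges the closest pair at each step (unweighted average of all
    cross-pair distances). Returns the merge history as a list of
    (frozenset of leaves, merge height), which identifies the tree
    independent of any leaf-ordering convention.
    """
    clusters = [[l] for l in sorted(values)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([abs(values[a] - values[b])
                             for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        merges.append((frozenset(clusters[i]), float(d)))
    return merges
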