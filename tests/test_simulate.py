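"""Synthetic two-population generator: construction rules and sampling laws."""

import numpy as np
import pytest

from hlabag import (SimulationConfig, derive_enriched_population,
                    sample_cohort, simulate_phenotypes, simulate_population)


@pytest.fixture(scope="module")
def pops():
    cfg = SimulationConfig()
    base = simulate_population(cfg, 11, loci=("A", "B"))
    iso = derive_enriched_population(base, cfg, 12)
    return cfg, base, iso


def test_population_is_deterministic_given_seed():
    cfg = SimulationConfig()
    p1 = simulate_population(cfg, 5, loci=("A",))
    p2 = simulate_population(cfg, 5, loci=("A",))
    np.testing.assert_array_equal(p1.loci["A"].snp_alleles,
                                  p2.loci["A"].snp_alleles)
    np.testing.assert_array_equal(p1.loci["A"].freq, p2.loci["A"].freq)
    assert p1.loci["A"].hla_labels == p2.loci["A"].hla_labels


def test_frequencies_sum_to_one_and_alleles_covered(pops):
    cfg, base, iso = pops
    for pop in (base, iso):
        for locus, pool in pop.loci.items():
            assert abs(pool.freq.sum() - 1.0) < 1e-12
            assert len(set(pool.hla_labels)) == cfg.n_alleles


def test_each_haplotype_gets_distinct_allele_when_counts_match():
    cfg = SimulationConfig(n_alleles=6, n_shared_haplotypes=6)
    pop = simulate_population(cfg, 3, loci=("A",))
    assert len(set(pop.loci["A"].hla_labels)) == 6


def test_too_many_alleles_for_haplotypes_is_an_error():
    cfg = SimulationConfig(n_alleles=31, n_shared_haplotypes=30)
    with pytest.raises(ValueError, match="cannot cover"):
        simulate_population(cfg, 1, loci=("A",))


def test_enriched_mass_and_base_exclusivity(pops):
    cfg, base, iso = pops
    for locus, pool in iso.loci.items():
        flags = np.array(pool.flags)
        enriched_mass = pool.freq[flags == "enriched"].sum()
        assert abs(enriched_mass - cfg.enriched_mass) < 1e-12
        assert len(pool.freq) == len(base.loci[locus].freq) + cfg.n_enriched_haplotypes
    # base population carries no enriched haplotype
    for hid in iso.enriched_ids():
        locus = hid.split(":")[0]
        assert iso.haplotype_frequency(locus, hid) > 0
        assert base.haplotype_frequency(locus, hid) == 0.0


def test_shared_haplotypes_identical_between_populations(pops):
    cfg, base, iso = pops
    for locus in base.loci:
        n_shared = len(base.loci[locus].ids)
        np.testing.assert_array_equal(iso.loci[locus].snp_alleles[:n_shared],
                                      base.loci[locus].snp_alleles)
        assert iso.loci[locus].hla_labels[:n_shared] == base.loci[locus].hla_labels
        assert iso.loci[locus].ids[:n_shared] == base.loci[locus].ids


def test_noiseless_genotypes_equal_haplotype_sums(pops):
    cfg, base, iso = pops
    quiet = SimulationConfig(genotype_noise=0.0)
    cohort = sample_cohort(iso, 40, quiet, 77)
    hap = cohort.truth_haplotypes.set_index(["sample", "locus"])
    for locus, pool in iso.loci.items():
        idx = {h: i for i, h in enumerate(pool.ids)}
        cols = [cohort.genotypes.snp_index()[s] for s in iso.snp_ids[locus]]
        for i, s in enumerate(cohort.genotypes.samples):
            h1, h2 = hap.loc[(s, locus)]
            expected = pool.snp_alleles[idx[h1]] + pool.snp_alleles[idx[h2]]
            np.testing.assert_array_equal(cohort.genotypes.dosage[i, cols],
                                          expected)
            # typing matches the drawn haplotypes' labels
            want = tuple(sorted((pool.hla_labels[idx[h1]],
                                 pool.hla_labels[idx[h2]])))
            assert cohort.truth.get(s, locus) == want


def test_homozygous_draw_repeats_the_allele(pops):
    cfg, base, iso = pops
    cohort = sample_cohort(iso, 200, cfg, 78)
    hap = cohort.truth_haplotypes
    same = hap[hap.hap1 == hap.hap2]
    assert len(same) > 0
    for r in same.itertuples(index=False):
        pair = cohort.truth.get(r.sample, r.locus)
        assert pair[0] == pair[1]


def test_cohort_allele_frequencies_match_population():
    """Observed allele frequencies stay within 3 binomial SE of the pool's."""
    cfg = SimulationConfig()
    pop = simulate_population(cfg, 21, loci=("A",))
    n = 20_000
    cohort = sample_cohort(pop, n, cfg, 22)
    counts: dict[str, int] = {}
    for s in cohort.genotypes.samples:
        for a in cohort.truth.get(s, "A"):
            counts[a] = counts.get(a, 0) + 1
    truth_freq = pop.allele_frequencies("A")
    for allele, f in truth_freq.items():
        obs = counts.get(allele, 0) / (2 * n)
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert abs(obs - f) < 3 * se + 1e-9, allele


def test_phenotype_prevalence_matches_intercept():
    cfg = SimulationConfig()
    pop = simulate_population(cfg, 31, loci=("A",))
    cohort = sample_cohort(pop, 10_000, cfg, 32)
    phen = simulate_phenotypes(cohort.truth, {}, seed=33)
    frac = phen["status"].mean()
    se = np.sqrt(0.1 * 0.9 / 10_000)
    assert abs(frac - 0.10) < 3 * se


def test_planted_effect_raises_carriage_odds():
    cfg = SimulationConfig()
    pop = simulate_population(cfg, 41, loci=("A",))
    cohort = sample_cohort(pop, 10_000, cfg, 42)
    allele = max(pop.allele_frequencies("A").items(), key=lambda kv: kv[1])[0]
    phen = simulate_phenotypes(cohort.truth, {allele: 1.0}, seed=43)
    carrier = np.array([allele in cohort.truth.get(s, "A")
                        for s in phen["sample"]])
    status = phen["status"].to_numpy().astype(bool)
    tab = np.array([[np.sum(carrier & status), np.sum(carrier & ~status)],
                    [np.sum(~carrier & status), np.sum(~carrier & ~status)]],
                   dtype=float)
    odds_ratio = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
    assert odds_ratio > 1.0


def test_phenotypes_deterministic_and_reject_unknown_alleles():
    cfg = SimulationConfig()
    pop = simulate_population(cfg, 51, loci=("A",))
    cohort = sample_cohort(pop, 100, cfg, 52)
    p1 = simulate_phenotypes(cohort.truth, {}, seed=53)
    p2 = simulate_phenotypes(cohort.truth, {}, seed=53)
    assert p1.equals(p2)
    with pytest.raises(ValueError, match="absent"):
        simulate_phenotypes(cohort.truth, {"Z*99:99": 1.0}, seed=54)
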