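"""Attribute-bagging engine: training contracts, posteriors, persistence."""

import numpy as np
import pandas as pd
import pytest

from hlabag import (Classifier, GenotypeMatrix, HLATyping, LocusModel,
                    ModelFormatError, RunConfig, SimulationConfig,
                    HLAImputationModel, HLAImputationResults,
                    impute, impute_in_batches, load_model, save_model,
                    sample_cohort, simulate_population, train_locus_model)


def _homozygous_training(n_haps=5, n_snps=6, copies=12, seed=0):
    """Training cohort of pure homozygotes over a known haplotype pool."""
    rng = np.random.default_rng(seed)
    pats = rng.integers(0, 2, size=(n_haps, n_snps))
    while len(np.unique((pats * (1 << np.arange(n_snps))).sum(1))) < n_haps:
        pats = rng.integers(0, 2, size=(n_haps, n_snps))
    labels = [f"A*{i + 1:02d}:01" for i in range(n_haps)]
    samples, rows = [], []
    t = HLATyping()
    for h in range(n_haps):
        for c in range(copies):
            s = f"H{h}_{c}"
            samples.append(s)
            rows.append(2 * pats[h])
            t.set(s, "A", labels[h], labels[h])
    g = GenotypeMatrix(samples, [f"rs{j}" for j in range(n_snps)],
                       np.arange(n_snps) + 1, ["A"] * n_snps, ["G"] * n_snps,
                       np.array(rows, dtype=np.int8))
    return g, t, pats, labels


def test_model_has_requested_classifier_count():
    g, t, _, _ = _homozygous_training()
    cfg = RunConfig(n_classifiers=100, greedy_moves=0)
    m = train_locus_model(g, t, "A", cfg, seed=1)
    assert len(m.classifiers) == 100


def test_perfect_tag_snp_gives_oob_accuracy_one():
    """A SNP that separates the two alleles by itself yields OOB accuracy 1."""
    rng = np.random.default_rng(5)
    n = 80
    tag = rng.integers(0, 2, size=n)
    noise = rng.integers(0, 3, size=(n, 1))
    g = GenotypeMatrix([f"S{i}" for i in range(n)], ["tag", "junk"],
                       np.array([1, 2]), ["A", "A"], ["G", "G"],
                       np.column_stack([2 * tag, noise]).astype(np.int8))
    t = HLATyping()
    for i in range(n):
        a = "A*01:01" if tag[i] else "A*02:01"
        t.set(f"S{i}", "A", a, a)
    cfg = RunConfig(n_classifiers=5, subset_size=2, greedy_moves=0)
    m = train_locus_model(g, t, "A", cfg, seed=2)
    for c in m.classifiers:
        assert "tag" in c.snp_ids
        assert c.oob_accuracy == pytest.approx(1.0)


def test_training_is_deterministic_given_seed():
    cfg = SimulationConfig(n_snps=12, n_alleles=4, n_shared_haplotypes=8)
    pop = simulate_population(cfg, 9, loci=("A",))
    coh = sample_cohort(pop, 120, cfg, 10)
    run = RunConfig(n_classifiers=4)
    m1 = train_locus_model(coh.genotypes, coh.truth, "A", run, seed=3)
    m2 = train_locus_model(coh.genotypes, coh.truth, "A", run, seed=3)
    for c1, c2 in zip(m1.classifiers, m2.classifiers):
        assert c1.snp_ids == c2.snp_ids
        np.testing.assert_array_equal(c1.patterns, c2.patterns)
        np.testing.assert_array_equal(c1.freq, c2.freq)
        assert c1.oob_accuracy == c2.oob_accuracy


def test_monomorphic_locus_is_rejected():
    g, t, _, _ = _homozygous_training(n_haps=1)
    with pytest.raises(ValueError, match="monomorphic"):
        train_locus_model(g, t, "A", RunConfig(n_classifiers=2), seed=0)


def test_posteriors_normalize_and_stay_in_training_alleles(small_run):
    """Each sample's posterior over pairs sums to 1; called alleles always
    come from the panel's training allele set."""
    for locus, model in small_run.matched.models.items():
        post, usable = model.posterior(small_run.test_cohort.genotypes)
        ok = usable > 0
        np.testing.assert_allclose(post[ok].sum(axis=1), 1.0, atol=1e-9)
    allowed = {locus: set(m.alleles)
               for locus, m in small_run.matched.models.items()}
    calls = small_run.calls_matched.calls.dropna(subset=["allele1"])
    for r in calls.itertuples(index=False):
        assert r.allele1 in allowed[r.locus]
        assert r.allele2 in allowed[r.locus]


def test_single_classifier_posterior_matches_hand_computation():
    """2-SNP table with known frequencies: posterior equals the ratio of
    haplotype-pair frequency products (x2 for heterozygous pairs)."""
    clf = Classifier(["s1", "s2"],
                     np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=np.uint8),
                     np.array(["A*01:01", "A*01:01", "A*02:01", "A*03:01"],
                              dtype=object),
                     np.array([0.4, 0.1, 0.3, 0.2]), 1.0)
    model = LocusModel("A", ["A*01:01", "A*02:01", "A*03:01"], [clf], 4)
    g = GenotypeMatrix(["S1"], ["s1", "s2"], np.array([1, 2]),
                       ["A", "A"], ["G", "G"], np.array([[1, 1]], dtype=np.int8))
    post, usable = model.posterior(g)
    pairs = model.pairs()
    by_pair = dict(zip(pairs, post[0]))
    # genotype (1,1) decomposes as {00,11} -> 01:01/01:01 (2*0.4*0.1 = 0.08)
    # or {01,10} -> 02:01/03:01 (2*0.3*0.2 = 0.12); total 0.20
    assert by_pair[("A*01:01", "A*01:01")] == pytest.approx(0.4, abs=1e-12)
    assert by_pair[("A*02:01", "A*03:01")] == pytest.approx(0.6, abs=1e-12)


def test_unique_diplotype_match_gives_posterior_one():
    g, t, pats, labels = _homozygous_training()
    cfg = RunConfig(n_classifiers=3, subset_size=6, greedy_moves=0)
    m = train_locus_model(g, t, "A", cfg, seed=4)
    target = GenotypeMatrix(["T1"], g.snp_ids, np.arange(6) + 1,
                            g.ref, g.alt, (2 * pats[[0]]).astype(np.int8))
    calls = impute({"A": m}, target).calls
    assert calls.iloc[0]["allele1"] == calls.iloc[0]["allele2"] == labels[0]
    assert calls.iloc[0]["posterior"] == pytest.approx(1.0, abs=1e-9)


def test_homozygous_training_equals_table_lookup():
    """One classifier over all SNPs, homozygous training: imputation is a
    nearest-haplotype lookup by exact pattern match."""
    g, t, pats, labels = _homozygous_training(n_haps=6, n_snps=8, seed=3)
    cfg = RunConfig(n_classifiers=1, subset_size=8, greedy_moves=0)
    m = train_locus_model(g, t, "A", cfg, seed=5)
    rng = np.random.default_rng(6)
    draws = rng.integers(0, 6, size=(20, 2))
    target_dos = (pats[draws[:, 0]] + pats[draws[:, 1]]).astype(np.int8)
    target = GenotypeMatrix([f"T{i}" for i in range(20)], g.snp_ids,
                            np.arange(8) + 1, g.ref, g.alt, target_dos)
    calls = impute({"A": m}, target).calls
    for i in range(20):
        want = tuple(sorted((labels[draws[i, 0]], labels[draws[i, 1]])))
        got = (calls.iloc[i]["allele1"], calls.iloc[i]["allele2"])
        assert got == want


def test_sample_with_no_usable_classifier_is_flagged():
    g, t, pats, labels = _homozygous_training()
    cfg = RunConfig(n_classifiers=2, subset_size=6, greedy_moves=0)
    m = train_locus_model(g, t, "A", cfg, seed=7)
    target = GenotypeMatrix(["T1"], ["other1", "other2"], np.array([1, 2]),
                            ["A", "A"], ["G", "G"],
                            np.array([[1, 1]], dtype=np.int8))
    calls = impute({"A": m}, target).calls
    assert pd.isna(calls.iloc[0]["allele1"])
    assert calls.iloc[0]["posterior"] == 0.0


def test_batched_imputation_equals_unbatched(small_run):
    g = small_run.test_cohort.genotypes
    models = small_run.matched.models
    whole = impute(models, g).calls
    parts = impute_in_batches(models, g, n_batches=7).calls
    assert sorted(parts["batch"].unique()) == list(range(7))
    sizes = parts.groupby("batch")["sample"].nunique()
    assert sizes.max() - sizes.min() <= 1
    pd.testing.assert_frame_equal(
        whole.drop(columns="batch").reset_index(drop=True),
        parts.drop(columns="batch").reset_index(drop=True))
    with pytest.raises(ValueError, match="batches"):
        impute_in_batches(models, g, n_batches=g.n_samples + 1)


def test_model_archive_round_trips_bit_identically(small_run, tmp_path):
    models = small_run.matched.models
    cfg = small_run.matched.config
    path = tmp_path / "model.json"
    save_model(models, path, cfg)
    loaded, cfg2 = load_model(path)
    assert cfg2.to_dict() == cfg.to_dict()
    for locus, m in models.items():
        l2 = loaded[locus]
        assert l2.alleles == m.alleles and l2.n_train == m.n_train
        for c1, c2 in zip(m.classifiers, l2.classifiers):
            assert c1.snp_ids == c2.snp_ids
            assert c1.oob_accuracy == c2.oob_accuracy
            np.testing.assert_array_equal(c1.patterns, c2.patterns)
            np.testing.assert_array_equal(c1.alleles, c2.alleles)
            np.testing.assert_array_equal(c1.freq, c2.freq)  # bit identity
    # posteriors from the loaded model equal in-memory posteriors
    g = small_run.test_cohort.genotypes.subset_samples(
        small_run.test_cohort.genotypes.samples[:10])
    before = impute(models, g).calls
    after = impute(loaded, g).calls
    pd.testing.assert_frame_equal(before, after)


def test_tampered_archive_version_is_refused(small_run, tmp_path):
    path = tmp_path / "model.json"
    small_run.matched.save(path)
    text = path.read_text().replace('"version": 1', '"version": 99')
    path.write_text(text)
    with pytest.raises(ModelFormatError):
        HLAImputationResults.load(path)


def test_full_snp_classifiers_are_at_least_as_confident():
    """Mean posterior of correct calls does not decrease when classifier
    subsets are enlarged to the whole (noiseless) SNP block."""
    wins = 0
    for seed in range(5):
        sim = SimulationConfig(n_snps=12, n_alleles=4,
                               n_shared_haplotypes=10, genotype_noise=0.0)
        pop = simulate_population(sim, 60 + seed, loci=("A",))
        ref = sample_cohort(pop, 250, sim, 70 + seed)
        test = sample_cohort(pop, 80, sim, 80 + seed, sample_prefix="T")
        posts = {}
        for label, size in (("sqrt", None), ("full", 12)):
            run = RunConfig(n_classifiers=8, subset_size=size)
            res = HLAImputationModel.from_cohort(ref, run).fit(
                seed=90 + seed, loci=("A",))
            calls = res.impute(test.genotypes).calls
            correct = [r.posterior for r in calls.itertuples(index=False)
                       if tuple(sorted((r.allele1, r.allele2)))
                       == test.truth.get(r.sample, r.locus)]
            posts[label] = np.mean(correct)
        if posts["full"] >= posts["sqrt"] - 1e-9:
            wins += 1
    assert wins >= 4
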