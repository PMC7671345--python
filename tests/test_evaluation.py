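"""Error counting, bootstraps, permutation tests, ROC, sweeps, attribution."""

import numpy as np
import pandas as pd
import pytest

from hlabag import (ErrorTable, HLATyping, attribute_errors_to_haplotypes,
                    bestpp_reference_selection, bootstrap_error_distribution,
                    count_errors, permutation_test_sweep,
                    permutation_test_total_errors, roc_auc, threshold_sweep)
from hlabag.workflows import exchangeable_error_tables


def _calls(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "allele1",
                                       "allele2", "posterior"])


def _truth(entries):
    t = HLATyping()
    for s, locus, a1, a2 in entries:
        t.set(s, locus, a1, a2)
    return t


@pytest.mark.parametrize("truth_pair,called_pair,want", [
    (("A*01:01", "A*02:01"), ("A*02:01", "A*01:01"), 0),  # unordered match
    (("A*01:01", "A*02:01"), ("A*01:01", "A*03:01"), 1),  # one mismatch
    (("A*01:01", "A*01:01"), ("A*01:01", "A*02:01"), 1),  # homozygote truth
    (("A*01:01", "A*01:01"), ("A*02:01", "A*02:01"), 2),
    (("A*01:01", "A*02:01"), ("A*01:01", "A*02:01"), 0),
])
def test_error_counts_use_multiset_matching(truth_pair, called_pair, want):
    t = _truth([("S1", "A", *truth_pair)])
    calls = _calls([("S1", "A", called_pair[0], called_pair[1], 0.9)])
    assert count_errors(t, calls).total_errors == want


def test_homozygote_matching_agrees_with_exhaustive_pairing(rng):
    """Multiset matching equals the best over both explicit assignments."""
    alleles = [f"A*{i:02d}:01" for i in range(1, 5)]
    for _ in range(200):
        tp = rng.choice(alleles, 2)
        cp = rng.choice(alleles, 2)
        t = _truth([("S1", "A", tp[0], tp[1])])
        got = count_errors(t, _calls([("S1", "A", cp[0], cp[1], 1.0)])).total_errors
        best = min(int(cp[0] != tp[0]) + int(cp[1] != tp[1]),
                   int(cp[0] != tp[1]) + int(cp[1] != tp[0]))
        assert got == best


def test_flagged_calls_score_two_errors_and_are_tallied():
    t = _truth([("S1", "A", "A*01:01", "A*02:01")])
    calls = _calls([("S1", "A", None, None, 0.0)])
    e = count_errors(t, calls)
    assert e.total_errors == 2 and e.n_flagged == 1


def test_error_identities_hold(small_run):
    e = small_run.errors_generic
    assert e.per_locus().sum() == e.total_errors
    assert e.per_sample().sum() == e.total_errors
    assert e.error_rate == e.total_errors / (2.0 * e.n_calls)


def test_bootstrap_of_error_free_table_is_degenerate():
    df = pd.DataFrame({"sample": ["S1", "S2"], "locus": ["A", "A"],
                       "errors": [0, 0], "posterior": [0.9, 0.8]})
    boot = bootstrap_error_distribution(ErrorTable(df), n_boot=50, seed=1)
    assert (boot.replicates.to_numpy() == 0).all()


def test_bootstrap_mean_tracks_point_estimate(small_run):
    e = small_run.errors_generic
    boot = bootstrap_error_distribution(e, n_boot=200, seed=2)
    per_locus = e.per_locus()
    for locus in boot.replicates.columns:
        reps = boot.replicates[locus]
        se = reps.std(ddof=1)
        assert abs(reps.mean() - per_locus[locus]) <= 3 * se + 1e-9
    again = bootstrap_error_distribution(e, n_boot=200, seed=2)
    pd.testing.assert_frame_equal(boot.replicates, again.replicates)


def _table(err_post, locus="A"):
    rows = [(f"S{i}", locus, e, p) for i, (e, p) in enumerate(err_post)]
    return ErrorTable(pd.DataFrame(rows, columns=["sample", "locus",
                                                  "errors", "posterior"]))


def test_permutation_test_on_identical_tables_gives_p_one():
    e = _table([(1, 0.5), (0, 0.9), (2, 0.3)])
    r = permutation_test_total_errors(e, e, n_perm=99, seed=0)
    assert r.observed == 0.0 and r.p_value == 1.0
    rs = permutation_test_sweep(e, e, [0.0, 0.4, 0.8], n_perm=99, seed=0)
    assert rs.observed == 0.0 and rs.p_value == 1.0


def test_extreme_separation_reaches_minimum_p():
    n = 200
    eA = _table([(0, 0.9)] * n)
    eB = _table([(2, 0.9)] * n)
    r = permutation_test_total_errors(eA, eB, n_perm=400, seed=1)
    assert r.observed == 2 * n
    assert r.p_value == pytest.approx(1.0 / 401.0)


def test_permutation_p_values_never_zero_and_calibrated():
    """Type-I error at alpha=0.05 stays within the 95% binomial band under
    a true exchangeable null (200 datasets, 200 permutations)."""
    rej = 0
    n_data = 200
    for i in range(n_data):
        eA, eB = exchangeable_error_tables(5_000 + i, n_samples=200,
                                           loci=tuple("ABCDEFG"))
        r = permutation_test_total_errors(eA, eB, n_perm=200, seed=i)
        assert r.p_value > 0.0
        if r.p_value < 0.05:
            rej += 1
    lo = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_data)
    hi = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_data)
    assert lo <= rej / n_data <= hi


def test_threshold_sweep_hand_count_and_monotonicity():
    e = _table([(2, 0.4), (1, 0.6), (0, 0.8), (0, 1.0)])
    grid = [0.0, 0.5, 0.9, 1.0]
    sweep = threshold_sweep(e, grid)
    assert sweep.loc[0, "retained_proportion"] == 1.0
    row = sweep.loc[1]  # t = 0.5 keeps three calls with errors (1,0,0)
    assert row["error_rate"] == pytest.approx(1.0 / 6.0)
    assert row["retained_proportion"] == pytest.approx(0.75)
    assert (np.diff(sweep["retained_proportion"]) <= 1e-12).all()


def test_sweep_statistic_sign_follows_dominant_panel():
    eA = _table([(0, 0.9)] * 10)
    eB = _table([(1, 0.9)] * 10)
    r = permutation_test_sweep(eA, eB, [0.0, 0.5], n_perm=99, seed=3)
    assert r.observed > 0


def test_roc_perfect_separation_and_hand_example():
    perfect = _table([(0, 0.95), (0, 0.9), (1, 0.2), (2, 0.1)])
    assert roc_auc(perfect).auc == 1.0
    toy = _table([(0, 0.9), (0, 0.8), (1, 0.7), (1, 0.95)])
    assert roc_auc(toy).auc == pytest.approx(0.5)
    with pytest.raises(ValueError, match="AUC undefined"):
        roc_auc(_table([(0, 0.9), (0, 0.8)]))


def test_roc_on_uninformative_scores_is_half(rng):
    pairs = [(int(rng.random() < 0.3), float(rng.random()))
             for _ in range(2000)]
    auc = roc_auc(_table(pairs)).auc
    assert abs(auc - 0.5) < 0.05


def test_rank_auc_equals_trapezoidal_area(rng):
    pairs = [(int(rng.random() < 0.4), float(rng.beta(2, 1)))
             for _ in range(500)]
    r = roc_auc(_table(pairs))
    trapezoid = float(np.trapezoid(r.tpr, r.fpr))
    assert abs(r.auc - trapezoid) < 1e-12


def _calls_with_posterior(err_table, offset=0.0):
    rows = []
    for r in err_table.data.itertuples(index=False):
        rows.append((r.sample, r.locus, "A*01:01", "A*01:01",
                     min(1.0, r.posterior + offset)))
    return _calls(rows)


def test_bestpp_selection_identity_and_dominance():
    truth = _truth([(f"S{i}", "A", "A*01:01", "A*01:01") for i in range(30)])
    good = _calls([(f"S{i}", "A", "A*01:01", "A*01:01", 0.95)
                   for i in range(30)])
    bad = _calls([(f"S{i}", "A", "A*01:01", "A*02:01", 0.55)
                  for i in range(30)])
    same = bestpp_reference_selection(good, good, truth, k=5, seed=0)
    assert (same["bestpp_errors"] == same["errors_A"]).all()
    dom = bestpp_reference_selection(good, bad, truth, k=5, seed=0)
    assert (dom["bestpp_errors"] == dom["errors_A"]).all()
    assert (dom["fold_picks"] == "AAAAA").all()


def test_bestpp_error_between_panel_errors(study_runs):
    """Per locus, the selected-reference error is sandwiched between the
    two panels' own errors in nearly every replicate."""
    ok = total = 0
    for run in study_runs[:10]:
        table = bestpp_reference_selection(run.calls_matched.calls,
                                           run.calls_generic.calls,
                                           run.test_cohort.truth, seed=0)
        for r in table.itertuples(index=False):
            total += 1
            lo = min(r.errors_A, r.errors_B)
            hi = max(r.errors_A, r.errors_B)
            ok += lo <= r.bestpp_errors <= hi
    assert ok / total >= 0.9


def test_error_attribution_boundary_cases():
    df = pd.DataFrame({"sample": ["S1", "S2"], "locus": ["A", "A"],
                       "errors": [2, 1], "posterior": [0.5, 0.6]})
    hap = pd.DataFrame({"sample": ["S1", "S2"], "locus": ["A", "A"],
                        "hap1": ["A:S000", "A:S001"],
                        "hap2": ["A:S002", "A:S003"]})
    none = attribute_errors_to_haplotypes(ErrorTable(df), hap, set())
    assert none.carrier_error_share == 0.0
    all_in = attribute_errors_to_haplotypes(ErrorTable(df), hap,
                                            {"A:S000", "A:S001"})
    assert all_in.carrier_error_share == 1.0
    assert all_in.n_samples_with_error == 2
    assert all_in.max_errors_per_sample == 2
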