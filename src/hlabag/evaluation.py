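"""Imputation accuracy statistics.

The unit of error is the allele: each imputed locus call is scored 0, 1 or
2 errors against the clinical-grade truth pair by maximum multiset
matching of unordered pairs.  On top of the per-call error table sit the
bootstrap error distributions per locus, paired permutation tests for the
difference in total errors between two reference panels, ROC/AUC of the
posterior probability as a correctness score, retention/error sweeps over
posterior thresholds, cross-validated best-posterior panel selection, and
the attribution of errors to carriers of population-enriched haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ErrorTable:
    """Per sample x locus allele error counts with call posteriors."""

    data: pd.DataFrame          # sample, locus, errors, posterior
    n_flagged: int = 0          # calls with a missing pair (scored 2 errors)
    panel: str | None = None

    @property
    def total_errors(self) -> int:
        return int(self.data["errors"].sum())

    @property
    def n_calls(self) -> int:
        return len(self.data)

    @property
    def error_rate(self) -> float:
        return self.total_errors / (2.0 * self.n_calls)

    def per_locus(self) -> pd.Series:
        return self.data.groupby("locus", sort=True)["errors"].sum()

    def per_sample(self) -> pd.Series:
        return self.data.groupby("sample", sort=True)["errors"].sum()


@dataclass
class PermutationResult:
    """Observed statistic, permutation replicates, two-sided p-value."""

    observed: float
    replicates: np.ndarray
    p_value: float


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame    # n_boot rows x loci columns
    summary: pd.DataFrame       # locus, median, q1, q3, iqr


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class AttributionResult:
    carrier_error_share: float
    carrier_fraction: float
    n_samples_with_error: int
    max_errors_per_sample: int
    per_sample_errors: pd.Series


def _pair_errors(called, truth) -> int:
    """2 minus the maximum multiset matching between unordered pairs."""
    t = list(truth)
    hits = 0
    for a in called:
        if a in t:
            t.remove(a)
            hits += 1
    return 2 - hits


def count_errors(truth, calls: pd.DataFrame,
                 panel: str | None = None) -> ErrorTable:
    """Score imputation calls against truth typings.

    Flagged calls (missing allele pair) are scored 2 errors and tallied
    separately in ``n_flagged``.  Every call's sample and locus must be
    present in the truth typing.
    """
    rows = []
    n_flagged = 0
    for r in calls.itertuples(index=False):
        true_pair = truth.get(r.sample, r.locus)
        if true_pair is None:
            raise ValueError(f"call for ({r.sample}, {r.locus}) has no truth typing")
        if pd.isna(r.allele1) or pd.isna(r.allele2):
            n_flagged += 1
            errors = 2
        else:
            errors = _pair_errors((r.allele1, r.allele2), true_pair)
        rows.append((r.sample, r.locus, errors, float(r.posterior)))
    df = pd.DataFrame(rows, columns=["sample", "locus", "errors", "posterior"])
    if df.duplicated(["sample", "locus"]).any():
        raise ValueError("duplicate (sample, locus) calls in error table")
    return ErrorTable(df, n_flagged=n_flagged, panel=panel)


def bootstrap_error_distribution(e: ErrorTable, n_boot: int = 100,
                                 seed: int = 0) -> BootstrapResult:
    """Bootstrap the per-locus total error counts, resampling samples.

    The resampling unit is the sample — all its loci move together, since
    errors within an individual are dependent.
    """
    rng = np.random.default_rng(seed)
    wide = e.data.pivot(index="sample", columns="locus", values="errors")
    mat = wide.to_numpy()
    n = mat.shape[0]
    reps = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = np.nansum(mat[idx], axis=0)
    rep_df = pd.DataFrame(reps, columns=wide.columns)
    q1 = rep_df.quantile(0.25)
    q3 = rep_df.quantile(0.75)
    summary = pd.DataFrame({"locus": wide.columns,
                            "median": rep_df.median().values,
                            "q1": q1.values, "q3": q3.values,
                            "iqr": (q3 - q1).values})
    return BootstrapResult(rep_df, summary)


def _aligned_sample_errors(eA: ErrorTable, eB: ErrorTable):
    a = eA.data.set_index(["sample", "locus"])["errors"]
    b = eB.data.set_index(["sample", "locus"])["errors"]
    if set(a.index) != set(b.index):
        raise ValueError("error tables cover different (sample, locus) sets")
    b = b.reindex(a.index)
    sa = a.groupby("sample").sum()
    sb = b.groupby("sample").sum()
    return sa.to_numpy(dtype=float), sb.to_numpy(dtype=float)


def permutation_test_total_errors(eA: ErrorTable, eB: ErrorTable,
                                  n_perm: int = 1000,
                                  seed: int = 0) -> PermutationResult:
    """Paired sign-flip permutation test for the panel difference in errors.

    Both panels impute the same samples, so the null swaps each sample's
    A/B labels independently with probability 1/2.  The statistic is
    total errors(B) minus total errors(A); the p-value is two-sided with
    the +1 convention, so it can never be zero.
    """
    sa, sb = _aligned_sample_errors(eA, eB)
    d = sb - sa
    observed = float(d.sum())
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, len(d)))
    reps = signs @ d
    p = (1.0 + np.sum(np.abs(reps) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(observed, reps, float(p))


def threshold_sweep(e: ErrorTable, grid) -> pd.DataFrame:
    """Error rate among retained calls and retained proportion per threshold.

    A call is retained when its posterior is at least the threshold; the
    error rate is erroneous alleles over 2 x retained calls (NaN when
    nothing is retained).
    """
    post = e.data["posterior"].to_numpy()
    err = e.data["errors"].to_numpy()
    n = len(e.data)
    rows = []
    for t in grid:
        keep = post >= t
        n_keep = int(keep.sum())
        rate = float(err[keep].sum() / (2.0 * n_keep)) if n_keep else np.nan
        rows.append((float(t), rate, n_keep / n, n_keep))
    return pd.DataFrame(rows, columns=["threshold", "error_rate",
                                       "retained_proportion", "n_retained"])


def permutation_test_sweep(eA: ErrorTable, eB: ErrorTable, grid,
                           n_perm: int = 1000, seed: int = 0
                           ) -> PermutationResult:
    """Permutation test on the sum over thresholds of error-rate differences.

    The statistic is sum_t (errorRate_B(t) - errorRate_A(t)); the null
    swaps each sample's entire (errors, posterior) record between panels,
    as in :func:`permutation_test_total_errors`.
    """
    a = eA.data.set_index(["sample", "locus"])
    b = eB.data.set_index(["sample", "locus"]).reindex(a.index)
    if b["errors"].isna().any():
        raise ValueError("error tables cover different (sample, locus) sets")
    samples = a.index.get_level_values("sample")
    uniq = samples.unique()
    s_map = {s: i for i, s in enumerate(uniq)}
    s_idx = np.array([s_map[s] for s in samples])
    n_s = len(uniq)
    grid = np.asarray(list(grid), dtype=float)

    def per_sample_terms(err, post):
        """Per threshold: per-sample retained error sums and retained counts."""
        retained = post[None, :] >= grid[:, None]          # (T, calls)
        err_term = retained * err[None, :]
        num = np.zeros((len(grid), n_s))
        den = np.zeros((len(grid), n_s))
        for t in range(len(grid)):
            num[t] = np.bincount(s_idx, err_term[t], minlength=n_s)
            den[t] = np.bincount(s_idx, retained[t], minlength=n_s)
        return num, den

    numA, denA = per_sample_terms(a["errors"].to_numpy(float),
                                  a["posterior"].to_numpy(float))
    numB, denB = per_sample_terms(b["errors"].to_numpy(float),
                                  b["posterior"].to_numpy(float))

    def statistic(swap):
        """swap: bool (n_s,) — samples whose A/B records are exchanged."""
        nA = np.where(swap[None, :], numB, numA).sum(axis=1)
        dA = np.where(swap[None, :], denB, denA).sum(axis=1)
        nB = np.where(swap[None, :], numA, numB).sum(axis=1)
        dB = np.where(swap[None, :], denA, denB).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rA = np.where(dA > 0, nA / (2.0 * dA), 0.0)
            rB = np.where(dB > 0, nB / (2.0 * dB), 0.0)
        return float(np.sum(rB - rA))

    observed = statistic(np.zeros(n_s, dtype=bool))
    rng = np.random.default_rng(seed)
    reps = np.array([statistic(rng.random(n_s) < 0.5) for _ in range(n_perm)])
    p = (1.0 + np.sum(np.abs(reps) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(observed, reps, float(p))


def roc_auc(e: ErrorTable) -> ROCResult:
    """ROC of the posterior probability as a correctness score.

    One or two errors are grouped into a single "erroneous" category and
    analysed against zero errors; a higher posterior should predict a
    correct call.  The AUC uses the rank (Mann-Whitney) formula with tie
    correction; the curve points come from scikit-learn.
    """
    from sklearn.metrics import roc_curve

    correct = (e.data["errors"].to_numpy() == 0)
    score = e.data["posterior"].to_numpy(float)
    n_pos = int(correct.sum())
    n_neg = len(correct) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: all calls share one outcome")
    ranks = rankdata(score)
    auc = (ranks[correct].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(correct.astype(int), score)
    return ROCResult(float(auc), fpr, tpr, thr)


def bestpp_reference_selection(callsA: pd.DataFrame, callsB: pd.DataFrame,
                               truth, k: int = 10, seed: int = 0
                               ) -> pd.DataFrame:
    """Cross-validated panel selection by mean posterior probability.

    Samples are split into ``k`` folds.  Per locus and fold, the panel with
    the higher mean posterior over the other k-1 folds is selected and its
    calls are scored on the held-out fold; errors accumulate over folds.
    Returns per-locus error counts of the selection scheme and of each
    panel, with the selected panel per fold recorded.
    """
    a = callsA.set_index(["sample", "locus"])
    b = callsB.set_index(["sample", "locus"]).reindex(a.index)
    samples = a.index.get_level_values("sample").unique().to_numpy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, k)
    loci = a.index.get_level_values("locus").unique()

    eA = count_errors(truth, callsA).data.set_index(["sample", "locus"])["errors"]
    eB = count_errors(truth, callsB).data.set_index(["sample", "locus"])["errors"]

    rows = []
    for locus in sorted(loci):
        scheme_errors = 0
        picks = []
        for f, held in enumerate(folds):
            held_set = set(samples[held])
            train_mask = [(s, locus) for s in samples if s not in held_set]
            held_keys = [(s, locus) for s in samples[held]]
            meanA = a.loc[train_mask, "posterior"].mean()
            meanB = b.loc[train_mask, "posterior"].mean()
            pick = "A" if meanA >= meanB else "B"
            picks.append(pick)
            err = eA if pick == "A" else eB
            scheme_errors += int(err.loc[held_keys].sum())
        rows.append((locus, scheme_errors,
                     int(eA.xs(locus, level="locus").sum()),
                     int(eB.xs(locus, level="locus").sum()),
                     "".join(picks)))
    return pd.DataFrame(rows, columns=["locus", "bestpp_errors",
                                       "errors_A", "errors_B", "fold_picks"])


def attribute_errors_to_haplotypes(e: ErrorTable,
                                   truth_haplotypes: pd.DataFrame,
                                   enriched_ids: set[str]
                                   ) -> AttributionResult:
    """Share of imputation errors carried by enriched-haplotype samples.

    A sample is a carrier if any of its true haplotypes (any locus) is in
    ``enriched_ids``.  Reports the carrier share of all errors, the carrier
    fraction of the cohort, the number of samples with at least one error
    and the maximum per-sample error count.
    """
    carriers = set()
    for r in truth_haplotypes.itertuples(index=False):
        if r.hap1 in enriched_ids or r.hap2 in enriched_ids:
            carriers.add(r.sample)
    per_sample = e.per_sample()
    total = per_sample.sum()
    in_carriers = per_sample[per_sample.index.isin(carriers)].sum()
    share = float(in_carriers / total) if total > 0 else 0.0
    cohort = per_sample.index
    carrier_fraction = float(np.mean([s in carriers for s in cohort]))
    return AttributionResult(share, carrier_fraction,
                             int((per_sample > 0).sum()),
                             int(per_sample.max()) if len(per_sample) else 0,
                             per_sample)
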