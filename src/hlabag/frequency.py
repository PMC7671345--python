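"""Validation of imputed allele frequencies against an independent reference.

When a biobank cohort is imputed in genotyping batches, each batch's
imputed HLA allele frequencies can be compared with clinical-grade
frequencies from an independent dataset.  Systematic per-allele deviations
flag imputation bias (or batch composition bias), and smaller batches are
expected to deviate more — a negative rank correlation between a batch's
mean absolute deviation and its retained allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class FrequencyTable:
    """Per-locus, per-allele frequencies with their allele-count denominators."""

    data: pd.DataFrame               # locus, allele, count, frequency
    denominators: dict[str, int]     # locus -> retained allele count (2 x calls)
    pp_cutoff: float = 0.0
    empty: bool = False              # nothing retained at this cutoff

    def frequency(self, locus: str, allele: str) -> float:
        sel = self.data[(self.data["locus"] == locus)
                        & (self.data["allele"] == allele)]
        return float(sel["frequency"].iloc[0]) if len(sel) else 0.0


def allele_frequencies(calls, pp_cutoff: float = 0.0) -> FrequencyTable:
    """Imputed (or truth) HLA allele frequencies at a posterior cutoff.

    ``calls`` is either a calls DataFrame (sample, locus, allele1, allele2,
    posterior) or an :class:`~hlabag.io.HLATyping`, whose entries count as
    posterior 1.  Each retained call contributes two alleles (homozygotes
    contribute the allele twice); the denominator per locus is twice the
    retained call count.
    """
    if hasattr(calls, "to_frame") and not isinstance(calls, pd.DataFrame):
        df = calls.to_frame()
        df["posterior"] = 1.0
    else:
        df = calls.copy()
    df = df.dropna(subset=["allele1", "allele2"])
    kept = df[df["posterior"] >= pp_cutoff]
    rows = []
    denominators: dict[str, int] = {}
    for locus, grp in kept.groupby("locus", sort=True):
        counts: dict[str, int] = {}
        for r in grp.itertuples(index=False):
            counts[r.allele1] = counts.get(r.allele1, 0) + 1
            counts[r.allele2] = counts.get(r.allele2, 0) + 1
        denom = 2 * len(grp)
        denominators[locus] = denom
        for allele in sorted(counts):
            rows.append((locus, allele, counts[allele], counts[allele] / denom))
    data = pd.DataFrame(rows, columns=["locus", "allele", "count", "frequency"])
    return FrequencyTable(data, denominators, pp_cutoff, empty=len(kept) == 0)


def compare_frequencies(batch_tables: list[FrequencyTable],
                        reference: FrequencyTable) -> pd.DataFrame:
    """Mean +- SD of (batch frequency - reference frequency) per allele.

    The allele universe is the union over batches and reference; alleles
    absent from a table count as frequency 0.  Output is sorted by absolute
    mean difference, descending; invariant to batch order.
    """
    universe = set(zip(reference.data["locus"], reference.data["allele"]))
    for t in batch_tables:
        universe |= set(zip(t.data["locus"], t.data["allele"]))
    rows = []
    for locus, allele in sorted(universe):
        ref = reference.frequency(locus, allele)
        diffs = np.array([t.frequency(locus, allele) - ref
                          for t in batch_tables])
        rows.append((locus, allele, ref, float(diffs.mean()),
                     float(diffs.std(ddof=0))))
    df = pd.DataFrame(rows, columns=["locus", "allele", "reference_frequency",
                                     "mean_difference", "sd_difference"])
    return df.reindex(df["mean_difference"].abs()
                      .sort_values(ascending=False).index).reset_index(drop=True)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    defined: bool
    per_batch: pd.DataFrame = field(default_factory=pd.DataFrame)


def deviation_vs_count_correlation(batch_tables: list[FrequencyTable],
                                   reference: FrequencyTable
                                   ) -> CorrelationResult:
    """Spearman correlation of per-batch mean |deviation| with allele count.

    The expected sign is negative: bigger batches deviate less.  With
    constant deviations or counts the correlation is undefined and reported
    as such rather than as a number.
    """
    universe = set(zip(reference.data["locus"], reference.data["allele"]))
    for t in batch_tables:
        universe |= set(zip(t.data["locus"], t.data["allele"]))
    devs, counts = [], []
    for t in batch_tables:
        d = [abs(t.frequency(l, a) - reference.frequency(l, a))
             for l, a in sorted(universe)]
        devs.append(float(np.mean(d)))
        counts.append(int(sum(t.denominators.values())))
    per_batch = pd.DataFrame({"mean_abs_deviation": devs,
                              "retained_alleles": counts})
    if len(set(devs)) < 2 or len(set(counts)) < 2:
        return CorrelationResult(np.nan, np.nan, False, per_batch)
    rho, p = spearmanr(devs, counts)
    return CorrelationResult(float(rho), float(p), True, per_batch)
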