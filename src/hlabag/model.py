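"""Attribute-bagging HLA imputation models.

Each locus is imputed by an ensemble of classifiers.  A classifier is a
random SNP subset (of size about the square root of the candidate count,
then refined by a few greedy grow/swap moves that must raise out-of-bag
accuracy) together with an extended-haplotype frequency table fitted by EM
on a bootstrap resample of the training cohort.  At prediction time each
classifier turns a sample's SNP genotype into a posterior over unordered
HLA allele pairs under Hardy-Weinberg pairing of table haplotypes;
classifier posteriors are averaged with weights proportional to out-of-bag
accuracy.  Alleles absent from the training panel can never be emitted —
the documented limitation of any reference-based imputation.

The user-facing surface follows the model/results idiom:
``HLAImputationModel(genotypes, typings, config).fit(seed)`` returns an
:class:`HLAImputationResults` that imputes, summarises and serialises.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .em import (MAX_EXPANSIONS, HaplotypeTable, em_haplotype_frequencies,
                 enumerate_pattern_pairs)
from .io import MISSING, GenotypeMatrix, HLATyping

log = logging.getLogger(__name__)

MODEL_FORMAT = "hlabag-model"
MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """A serialized model could not be loaded safely."""


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class Classifier:
    """One bagged classifier: SNP subset + extended-haplotype table."""

    snp_ids: list[str]
    patterns: np.ndarray        # (H, k) uint8
    alleles: np.ndarray         # (H,) object — HLA labels
    freq: np.ndarray            # (H,)
    oob_accuracy: float

    def __post_init__(self) -> None:
        if self.patterns.shape[1] != len(self.snp_ids):
            raise ValueError("pattern length must equal SNP subset size")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError("classifier frequencies must sum to 1 within 1e-9")

    def _lookup(self, allele_index: dict[str, int], n_alleles: int):
        """Sorted pattern codes with per-allele frequency rows, cached."""
        cache = getattr(self, "_lk", None)
        if cache is not None:
            return cache
        k = len(self.snp_ids)
        codes = np.zeros(len(self.freq), dtype=np.int64)
        for j in range(k):
            codes |= self.patterns[:, j].astype(np.int64) << j
        uniq = np.unique(codes)
        F = np.zeros((len(uniq), n_alleles))
        rows = np.searchsorted(uniq, codes)
        for r, a, f in zip(rows, self.alleles, self.freq):
            F[r, allele_index[a]] += f
        self._lk = (uniq, F)
        return self._lk

    def pair_scores(self, rows: np.ndarray, allele_index: dict[str, int],
                    n_alleles: int,
                    max_expansions: int = MAX_EXPANSIONS) -> np.ndarray:
        """Unnormalised scores over ordered allele-pair matrix per genotype row.

        ``rows`` is ``(n, k)`` with values 0/1/2/-1 over the classifier's
        SNP subset.  Returns ``(n, A, A)``; an all-zero slice marks a sample
        the classifier cannot score (pattern unseen, or all sites missing).
        """
        code_table, F = self._lookup(allele_index, n_alleles)
        n, k = rows.shape
        codes = (np.asarray(rows, dtype=np.int64) + 1) @ (4 ** np.arange(k, dtype=np.int64))
        uniq, inv = np.unique(codes, return_inverse=True)
        first = np.zeros(len(uniq), dtype=np.int64)
        first[inv] = np.arange(n)
        slices = np.zeros((len(uniq), n_alleles, n_alleles))
        top = len(code_table) - 1
        for u in range(len(uniq)):
            row = rows[first[u]]
            if np.all(row == MISSING):
                continue
            pairs = enumerate_pattern_pairs(row, max_expansions)
            if pairs is None:
                continue
            p1, p2 = pairs
            pos1 = np.searchsorted(code_table, p1).clip(max=top)
            pos2 = np.searchsorted(code_table, p2).clip(max=top)
            keep = (code_table[pos1] == p1) & (code_table[pos2] == p2)
            if not keep.any():
                continue
            slices[u] = F[pos1[keep]].T @ F[pos2[keep]]
        out = slices[inv]
        return out


# ---------------------------------------------------------------------------
# locus model
# ---------------------------------------------------------------------------

def _pair_list(alleles: list[str]) -> list[tuple[str, str]]:
    """All unordered allele pairs in lexicographic order."""
    return [(alleles[i], alleles[j])
            for i in range(len(alleles)) for j in range(i, len(alleles))]


@dataclass
class LocusModel:
    """Trained per-locus ensemble."""

    locus: str
    alleles: list[str]          # sorted training allele set
    classifiers: list[Classifier]
    n_train: int

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("empty training allele set")
        allowed = set(self.alleles)
        for c in self.classifiers:
            extra = set(c.alleles) - allowed
            if extra:
                raise ValueError(f"classifier carries alleles outside the "
                                 f"training set: {sorted(extra)}")

    @property
    def snps_used(self) -> list[str]:
        out: dict[str, None] = {}
        for c in self.classifiers:
            for s in c.snp_ids:
                out.setdefault(s)
        return list(out)

    def pairs(self) -> list[tuple[str, str]]:
        return _pair_list(self.alleles)

    def posterior(self, g: GenotypeMatrix,
                  weighting: str = "oob") -> tuple[np.ndarray, np.ndarray]:
        """Combined posterior over unordered allele pairs.

        Returns ``(post, n_usable)`` where ``post`` is
        ``(n_samples, n_pairs)`` (rows of flagged samples are all zero) and
        ``n_usable`` counts contributing classifiers per sample.
        """
        A = len(self.alleles)
        aidx = {a: i for i, a in enumerate(self.alleles)}
        iu = np.triu_indices(A)
        n = g.n_samples
        col_of = g.snp_index()
        combined = np.zeros((n, len(iu[0])))
        weight_sum = np.zeros(n)
        n_usable = np.zeros(n, dtype=int)
        for c in self.classifiers:
            cols = [col_of.get(s) for s in c.snp_ids]
            rows = np.full((n, len(c.snp_ids)), MISSING, dtype=np.int64)
            for j, col in enumerate(cols):
                if col is not None:
                    rows[:, j] = g.dosage[:, col]
            scores = c.pair_scores(rows, aidx, A)
            # fold the ordered (A, A) score matrix onto unordered pairs
            sym = scores + np.transpose(scores, (0, 2, 1))
            pair_scores = sym[:, iu[0], iu[1]]
            diag = iu[0] == iu[1]
            pair_scores[:, diag] /= 2.0
            totals = pair_scores.sum(axis=1)
            usable = totals > 0
            if not usable.any():
                continue
            w = c.oob_accuracy if weighting == "oob" else 1.0
            if w <= 0:
                w = 1e-6  # keep an uninformative classifier from vanishing
            post = np.zeros_like(pair_scores)
            post[usable] = pair_scores[usable] / totals[usable, None]
            combined[usable] += w * post[usable]
            weight_sum[usable] += w
            n_usable[usable] += 1
        ok = weight_sum > 0
        combined[ok] /= weight_sum[ok, None]
        return combined, n_usable


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _oob_accuracy(clf: Classifier, rows: np.ndarray, truth_pairs: list,
                  alleles: list[str]) -> float:
    """Allele-level accuracy of a single classifier on held-out samples."""
    if len(rows) == 0:
        return 0.0
    A = len(alleles)
    aidx = {a: i for i, a in enumerate(alleles)}
    iu = np.triu_indices(A)
    scores = clf.pair_scores(rows, aidx, A)
    sym = scores + np.transpose(scores, (0, 2, 1))
    pair_scores = sym[:, iu[0], iu[1]]
    pair_scores[:, iu[0] == iu[1]] /= 2.0
    totals = pair_scores.sum(axis=1)
    usable = totals > 0
    if not usable.any():
        return 0.0
    best = np.argmax(pair_scores[usable], axis=1)
    correct = 0
    idx_usable = np.flatnonzero(usable)
    for b, i in zip(best, idx_usable):
        called = (alleles[iu[0][b]], alleles[iu[1][b]])
        correct += _pair_overlap(called, truth_pairs[i])
    return correct / (2.0 * len(idx_usable))


def _pair_overlap(called: tuple[str, str], truth: tuple[str, str]) -> int:
    """Multiset overlap between two unordered allele pairs (0, 1 or 2)."""
    t = list(truth)
    hits = 0
    for a in called:
        if a in t:
            t.remove(a)
            hits += 1
    return hits


def _fit_classifier_table(D: np.ndarray, pairs: list, inbag: np.ndarray,
                          subset: np.ndarray, cfg: RunConfig) -> HaplotypeTable:
    geno = D[np.ix_(inbag, subset)]
    hla = [pairs[i] for i in inbag]
    return em_haplotype_frequencies(geno, hla, tol=cfg.em_tol,
                                    max_iter=cfg.em_max_iter,
                                    prune=cfg.freq_prune)


def train_locus_model(g: GenotypeMatrix, t: HLATyping, locus: str,
                      cfg: RunConfig, seed, candidate_snps=None) -> LocusModel:
    """Train one locus's attribute-bagging ensemble.

    Per classifier: bootstrap-resample the training samples, draw a random
    SNP subset of size ``ceil(sqrt(n_candidates))``, then apply up to
    ``cfg.greedy_moves`` grow/swap moves, each kept only if it raises the
    classifier's out-of-bag allele accuracy; the haplotype table is fitted
    by EM on the in-bag samples.  Deterministic given the seed.
    """
    pairs = []
    for s in g.samples:
        pair = t.get(s, locus)
        if pair is None:
            raise ValueError(f"training sample {s} is not typed at {locus}")
        pairs.append(pair)
    alleles = sorted({a for p in pairs for a in p})
    if len(alleles) < 2:
        raise ValueError(f"locus {locus} is monomorphic in the training data")

    if candidate_snps is None:
        candidate_snps = list(g.snp_ids)
    col_of = g.snp_index()
    cand_cols = [col_of[s] for s in candidate_snps if s in col_of]
    cand_ids = [s for s in candidate_snps if s in col_of]
    m = len(cand_cols)
    if m == 0:
        raise ValueError("no candidate SNPs present in the genotype matrix")
    D = g.dosage[:, cand_cols].astype(np.int64)
    n = g.n_samples
    size0 = cfg.subset_size or math.ceil(math.sqrt(m))
    size0 = min(size0, m, cfg.max_subset)

    rng = np.random.default_rng(seed)
    classifiers: list[Classifier] = []
    for _ in range(cfg.n_classifiers):
        inbag = np.sort(rng.integers(0, n, size=n))
        oob = np.setdiff1d(np.arange(n), inbag)
        oob_rows = D[np.ix_(oob, np.arange(m))]
        oob_truth = [pairs[i] for i in oob]

        subset = np.sort(rng.choice(m, size=size0, replace=False))
        table = _fit_classifier_table(D, pairs, inbag, subset, cfg)
        clf = _make_classifier(table, subset, cand_ids)
        acc = _oob_accuracy(clf, oob_rows[:, subset], oob_truth, alleles)

        for _move in range(cfg.greedy_moves):
            grow = (len(subset) < min(m, cfg.max_subset)
                    and rng.random() < 0.5)
            others = np.setdiff1d(np.arange(m), subset)
            if len(others) == 0:
                break
            new_snp = int(rng.choice(others))
            if grow:
                proposal = np.sort(np.append(subset, new_snp))
            else:
                drop = int(rng.choice(subset))
                proposal = np.sort(np.append(subset[subset != drop], new_snp))
            cand_table = _fit_classifier_table(D, pairs, inbag, proposal, cfg)
            cand_clf = _make_classifier(cand_table, proposal, cand_ids)
            cand_acc = _oob_accuracy(cand_clf, oob_rows[:, proposal],
                                     oob_truth, alleles)
            if cand_acc > acc:
                subset, clf, acc = proposal, cand_clf, cand_acc
        clf.oob_accuracy = acc
        classifiers.append(clf)
    return LocusModel(locus, alleles, classifiers, n)


def _make_classifier(table: HaplotypeTable, subset: np.ndarray,
                     cand_ids: list[str]) -> Classifier:
    return Classifier([cand_ids[j] for j in subset], table.patterns,
                      table.alleles, table.freq, 0.0)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """Best-guess calls plus (optionally) the full posterior table."""

    calls: pd.DataFrame                 # sample, locus, allele1, allele2, posterior, batch
    posteriors: pd.DataFrame | None = None  # sample, locus, allele1, allele2, prob

    @property
    def n_flagged(self) -> int:
        return int(self.calls["allele1"].isna().sum())


def impute(models: dict[str, LocusModel], g: GenotypeMatrix,
           weighting: str = "oob", full_posteriors: bool = False,
           batch: int = 0) -> ImputationSet:
    """Impute every locus of ``g`` with the given models.

    Flagged samples (no usable classifier) receive a missing pair with
    posterior 0.  Ties in the best-guess argmax break to the
    lexicographically smallest allele pair.
    """
    rows = []
    post_rows = []
    for locus, model in models.items():
        pairs = model.pairs()
        post, n_usable = model.posterior(g, weighting=weighting)
        # argmax returns the first maximum; pairs are lexicographically
        # ordered, so ties break to the smallest pair label
        best = np.argmax(post, axis=1)
        for i, s in enumerate(g.samples):
            if n_usable[i] == 0:
                rows.append((s, locus, None, None, 0.0, batch))
                continue
            a1, a2 = pairs[best[i]]
            rows.append((s, locus, a1, a2, float(post[i, best[i]]), batch))
            if full_posteriors:
                for j, (p1, p2) in enumerate(pairs):
                    if post[i, j] > 0:
                        post_rows.append((s, locus, p1, p2, float(post[i, j])))
    calls = pd.DataFrame(rows, columns=["sample", "locus", "allele1",
                                        "allele2", "posterior", "batch"])
    # canonical sample-major order, so batched runs concatenate identically
    s_order = {s: i for i, s in enumerate(g.samples)}
    l_order = {loc: i for i, loc in enumerate(models)}
    calls = (calls
             .sort_values(["sample", "locus"],
                          key=lambda col: (col.map(s_order) if col.name == "sample"
                                           else col.map(l_order)),
                          kind="stable")
             .reset_index(drop=True))
    posteriors = (pd.DataFrame(post_rows, columns=["sample", "locus",
                                                   "allele1", "allele2", "prob"])
                  if full_posteriors else None)
    return ImputationSet(calls, posteriors)


def impute_in_batches(models: dict[str, LocusModel], g: GenotypeMatrix,
                      n_batches: int, seed=None, weighting: str = "oob",
                      full_posteriors: bool = False) -> ImputationSet:
    """Impute in near-equal sample batches (sizes differ by at most one).

    Batching is an orchestration device: concatenated batch output equals
    unbatched output.  The batch label of each call is recorded for
    downstream per-batch frequency validation.
    """
    if n_batches > g.n_samples:
        raise ValueError("more batches than samples")
    splits = np.array_split(np.arange(g.n_samples), n_batches)
    sets = []
    for b, idx in enumerate(splits):
        sub = g.subset_samples([g.samples[i] for i in idx])
        sets.append(impute(models, sub, weighting=weighting,
                           full_posteriors=full_posteriors, batch=b))
    calls = pd.concat([s.calls for s in sets], ignore_index=True)
    posteriors = (pd.concat([s.posteriors for s in sets], ignore_index=True)
                  if full_posteriors else None)
    return ImputationSet(calls, posteriors)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(models: dict[str, LocusModel], path,
               config: RunConfig | None = None) -> None:
    """Write trained models as a versioned, diffable JSON archive."""
    tree = {"format": MODEL_FORMAT, "version": MODEL_VERSION,
            "config": (config or RunConfig()).to_dict(), "loci": {}}
    for locus, m in models.items():
        tree["loci"][locus] = {
            "alleles": m.alleles, "n_train": m.n_train,
            "classifiers": [
                {"snp_ids": c.snp_ids, "oob_accuracy": c.oob_accuracy,
                 "haplotypes": [
                     {"pattern": "".join(str(int(b)) for b in c.patterns[h]),
                      "allele": str(c.alleles[h]), "freq": float(c.freq[h])}
                     for h in range(len(c.freq))]}
                for c in m.classifiers]}
    with open(path, "w") as fh:
        json.dump(tree, fh, indent=1)


def load_model(path) -> tuple[dict[str, LocusModel], RunConfig]:
    """Load a model archive; refuses anything but the exact known version."""
    with open(path) as fh:
        tree = json.load(fh)
    if tree.get("format") != MODEL_FORMAT or tree.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unsupported model archive (format={tree.get('format')!r}, "
            f"version={tree.get('version')!r}); expected "
            f"{MODEL_FORMAT} v{MODEL_VERSION}")
    config = RunConfig.from_dict(tree["config"])
    models: dict[str, LocusModel] = {}
    for locus, node in tree["loci"].items():
        classifiers = []
        for cn in node["classifiers"]:
            haps = cn["haplotypes"]
            k = len(cn["snp_ids"])
            patterns = np.array([[int(ch) for ch in h["pattern"]] for h in haps],
                                dtype=np.uint8).reshape(len(haps), k)
            alleles = np.array([h["allele"] for h in haps], dtype=object)
            freq = np.array([h["freq"] for h in haps])
            classifiers.append(Classifier(list(cn["snp_ids"]), patterns,
                                          alleles, freq,
                                          float(cn["oob_accuracy"])))
        models[locus] = LocusModel(locus, list(node["alleles"]), classifiers,
                                   int(node["n_train"]))
    return models, config


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class HLAImputationModel:
    """Attribute-bagging imputation model over a reference cohort.

    Parameters
    ----------
    genotypes
        Reference-panel SNP genotypes.
    typings
        Clinical-grade two-field HLA typings of the same samples.
    config
        Run configuration; defaults apply if omitted.
    locus_snps
        Optional mapping locus -> candidate SNP IDs (the SNPs flanking the
        gene).  Without it every SNP is a candidate for every locus, which
        is only sensible for single-locus matrices.
    """

    def __init__(self, genotypes: GenotypeMatrix, typings: HLATyping,
                 config: RunConfig | None = None,
                 locus_snps: dict[str, list[str]] | None = None):
        self.genotypes = genotypes
        self.typings = typings
        self.config = config or RunConfig()
        self.locus_snps = locus_snps or {}

    @classmethod
    def from_cohort(cls, cohort, config: RunConfig | None = None):
        return cls(cohort.genotypes, cohort.truth, config,
                   locus_snps=cohort.locus_snps)

    def fit(self, seed: int | None = None,
            loci: tuple[str, ...] | None = None) -> "HLAImputationResults":
        from .simulate import as_seed_sequence
        cfg = self.config
        if loci is None:
            typed = set(self.typings.loci())
            loci = tuple(l for l in cfg.loci if l in typed)
            if not loci:
                raise ValueError("no configured locus is typed in the "
                                 "training data")
        else:
            loci = tuple(loci)
        root = as_seed_sequence(cfg.seed if seed is None else seed)
        models: dict[str, LocusModel] = {}
        for locus, child in zip(loci, root.spawn(len(loci))):
            models[locus] = train_locus_model(
                self.genotypes, self.typings, locus, cfg, child,
                candidate_snps=self.locus_snps.get(locus))
        return HLAImputationResults(models, cfg, model=self)


class HLAImputationResults:
    """Fitted per-locus models with imputation, summary and persistence."""

    def __init__(self, models: dict[str, LocusModel], config: RunConfig,
                 model: HLAImputationModel | None = None):
        self.models = models
        self.config = config
        self.model = model

    def impute(self, g: GenotypeMatrix, n_batches: int = 1,
               full_posteriors: bool = False) -> ImputationSet:
        if n_batches == 1:
            return impute(self.models, g,
                          weighting=self.config.classifier_weighting,
                          full_posteriors=full_posteriors)
        return impute_in_batches(self.models, g, n_batches,
                                 weighting=self.config.classifier_weighting,
                                 full_posteriors=full_posteriors)

    def summary(self) -> str:
        lines = ["Attribute-bagging HLA imputation model",
                 "=" * 54,
                 f"{'locus':<8}{'alleles':>8}{'classifiers':>12}"
                 f"{'SNPs used':>10}{'mean OOB acc':>14}",
                 "-" * 54]
        for locus, m in self.models.items():
            accs = [c.oob_accuracy for c in m.classifiers]
            lines.append(f"{locus:<8}{len(m.alleles):>8}"
                         f"{len(m.classifiers):>12}{len(m.snps_used):>10}"
                         f"{np.mean(accs):>14.3f}")
        total_snps = len({s for m in self.models.values() for s in m.snps_used})
        lines.append("-" * 54)
        lines.append(f"distinct SNPs used across loci: {total_snps}")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.models, path, self.config)

    @classmethod
    def load(cls, path) -> "HLAImputationResults":
        models, config = load_model(path)
        return cls(models, config)
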