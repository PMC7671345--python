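"""EM estimation of extended-haplotype frequencies.

An *extended haplotype* is a SNP allele pattern over a small SNP subset
together with an HLA allele label.  Given unphased SNP genotypes and known
(unordered) HLA allele pairs, the phase over the SNP subset is latent; the
standard EM for haplotype frequencies applies, with each individual
distributed over all extended-haplotype pairs consistent with its genotype
and its HLA pair.  Missing SNP sites are marginalised by summing over both
alleles on each of the two haplotypes.

The implementation collapses individuals with identical (genotype, HLA
pair) keys, so its cost scales with the number of distinct diplotype keys
rather than the sample count.  SNP patterns are bit-encoded; subsets are
limited to 25 SNPs (the pattern-enumeration bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_SUBSET = 25
MAX_EXPANSIONS = 4096  # per-individual cap on enumerated haplotype pairs


@dataclass
class HaplotypeTable:
    """Fitted extended-haplotype frequency table.

    ``patterns[i]`` is the 0/1 SNP allele vector of haplotype ``i`` over the
    SNP subset, ``alleles[i]`` its HLA label and ``freq[i]`` its frequency.
    """

    patterns: np.ndarray         # (H, k) uint8
    alleles: np.ndarray          # (H,) object labels
    freq: np.ndarray             # (H,) sums to 1
    loglik: float
    n_iter: int
    converged: bool
    n_dropped: int               # individuals outside the enumeration bound

    def __post_init__(self) -> None:
        s = self.freq.sum()
        if self.freq.size and abs(s - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1 within 1e-9")


@dataclass
class _Problem:
    e1: np.ndarray               # support index of first haplotype, per pair
    e2: np.ndarray
    key_of_pair: np.ndarray      # which diplotype key each pair belongs to
    key_weight: np.ndarray       # individuals per key
    key_het_hla: np.ndarray      # bool: HLA pair heterozygous (likelihood x2)
    support_codes: np.ndarray    # (S,) encoded (pattern, allele)
    n_alleles: int
    k: int
    n_dropped: int
    n_used: float                # total individual weight retained


def _encode_rows(genotypes: np.ndarray) -> np.ndarray:
    """Base-4 encode genotype rows (values 0/1/2/-1 -> digits 1/2/3/0)."""
    g = np.asarray(genotypes, dtype=np.int64) + 1
    k = g.shape[1]
    weights = 4 ** np.arange(k, dtype=np.int64)
    return g @ weights


def _decode_row(code: int, k: int) -> np.ndarray:
    digits = np.empty(k, dtype=np.int64)
    for j in range(k):
        digits[j] = code % 4
        code //= 4
    return digits - 1


def _spread(masks: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Scatter the low bits of each mask onto the given bit positions."""
    bits = (masks[:, None] >> np.arange(len(positions))) & 1
    return bits @ (1 << positions.astype(np.int64))


_enum_cache: dict[bytes, tuple | None] = {}


def enumerate_pattern_pairs(row: np.ndarray,
                            max_expansions: int = MAX_EXPANSIONS):
    """Ordered pairs of bit-encoded SNP patterns consistent with a genotype row.

    Heterozygous sites contribute complementary assignments; missing sites
    are expanded over both alleles on each haplotype, so both orders of
    every assignment appear.  Returns a pair of int64 arrays, or ``None``
    when the expansion exceeds ``max_expansions``.  Results are memoised on
    the genotype row (training and out-of-bag scoring share SNP subsets,
    so rows recur).
    """
    row = np.asarray(row, dtype=np.int64)
    ckey = (row.tobytes(), max_expansions)
    if ckey in _enum_cache:
        return _enum_cache[ckey]
    result = _enumerate_pattern_pairs(row, max_expansions)
    if len(_enum_cache) > 250_000:
        _enum_cache.clear()
    _enum_cache[ckey] = result
    return result


def _enumerate_pattern_pairs(row: np.ndarray, max_expansions: int):
    het = np.flatnonzero(row == 1)
    mis = np.flatnonzero(row == -1)
    n_combo = (1 << len(het)) << (2 * len(mis))
    if n_combo > max_expansions:
        return None
    hom2 = np.flatnonzero(row == 2)
    base = int(np.sum(1 << hom2.astype(np.int64))) if len(hom2) else 0
    het_masks = np.arange(1 << len(het))
    p1h = base + _spread(het_masks, het)
    p2h = base + _spread((~het_masks) & ((1 << len(het)) - 1), het)
    if len(mis) == 0:
        return p1h.astype(np.int64), p2h.astype(np.int64)
    mis_masks = np.arange(1 << len(mis))
    mis_add = _spread(mis_masks, mis)
    # cross het assignments with independent missing-site fills per haplotype
    p1 = (p1h[:, None, None] + mis_add[None, :, None]
          + np.zeros_like(mis_add)[None, None, :]).ravel()
    p2 = (p2h[:, None, None] + np.zeros_like(mis_add)[None, :, None]
          + mis_add[None, None, :]).ravel()
    return p1.astype(np.int64), p2.astype(np.int64)


def _prepare(genotypes: np.ndarray, hla_pairs, max_expansions: int) -> tuple:
    """Collapse individuals into diplotype keys and enumerate pair arrays."""
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[0] == 0:
        raise ValueError("genotypes must be a non-empty 2-D array")
    n, k = g.shape
    if k > MAX_SUBSET:
        raise ValueError(f"SNP subset of {k} exceeds the enumeration bound "
                         f"of {MAX_SUBSET}")
    if len(hla_pairs) != n:
        raise ValueError("one HLA pair per genotype row is required")
    labels = sorted({a for pair in hla_pairs for a in pair})
    code_of = {a: i for i, a in enumerate(labels)}
    A = len(labels)
    a1 = np.array([code_of[min(p)] for p in hla_pairs], dtype=np.int64)
    a2 = np.array([code_of[max(p)] for p in hla_pairs], dtype=np.int64)
    geno_codes = _encode_rows(g)
    scalar = (geno_codes * A + a1) * A + a2  # injective for k <= 25
    order, first_idx, counts = np.unique(scalar, return_index=True,
                                         return_counts=True)
    uniq = np.stack([geno_codes[first_idx], a1[first_idx], a2[first_idx]],
                    axis=1)

    e1_list, e2_list, pair_key = [], [], []
    key_weight, key_het = [], []
    pattern_cache: dict[int, tuple] = {}
    n_dropped = 0
    kk = 0
    for u_row, src, cnt in zip(uniq, first_idx, counts):
        code = int(u_row[0])
        if code not in pattern_cache:
            pattern_cache[code] = enumerate_pattern_pairs(g[src], max_expansions)
        pairs = pattern_cache[code]
        if pairs is None:
            n_dropped += int(cnt)
            continue
        p1, p2 = pairs
        ca1, ca2 = int(u_row[1]), int(u_row[2])
        e1_list.append(p1 * A + ca1)
        e2_list.append(p2 * A + ca2)
        pair_key.append(np.full(len(p1), kk, dtype=np.int64))
        key_weight.append(float(cnt))
        key_het.append(ca1 != ca2)
        kk += 1
    if kk == 0:
        raise ValueError("no individual admits a consistent haplotype pair "
                         "within the enumeration bound")
    e1 = np.concatenate(e1_list)
    e2 = np.concatenate(e2_list)
    support, inv = np.unique(np.concatenate([e1, e2]), return_inverse=True)
    e1_idx = inv[: len(e1)]
    e2_idx = inv[len(e1):]
    prob = _Problem(e1_idx, e2_idx, np.concatenate(pair_key),
                    np.array(key_weight), np.array(key_het, dtype=bool),
                    support, A, k, n_dropped, float(np.sum(key_weight)))
    return prob, labels


def _loglik(prob: _Problem, f: np.ndarray) -> float:
    pw = f[prob.e1] * f[prob.e2]
    ssum = np.bincount(prob.key_of_pair, pw, minlength=len(prob.key_weight))
    ssum = np.where(prob.key_het_hla, 2.0 * ssum, ssum)
    with np.errstate(divide="ignore"):
        logs = np.log(ssum)
    return float(np.dot(prob.key_weight, logs))


def _em_core(prob: _Problem, f0: np.ndarray, tol: float,
             max_iter: int) -> tuple[np.ndarray, int, bool]:
    f = f0.copy()
    e1, e2, key = prob.e1, prob.e2, prob.key_of_pair
    K = len(prob.key_weight)
    total = 2.0 * prob.key_weight.sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pw = f[e1] * f[e2]
        ssum = np.bincount(key, pw, minlength=K)
        safe = np.where(ssum > 0, ssum, 1.0)
        gamma = pw / safe[key]
        wg = gamma * prob.key_weight[key]
        newf = (np.bincount(e1, wg, minlength=len(f))
                + np.bincount(e2, wg, minlength=len(f))) / total
        delta = np.max(np.abs(newf - f))
        f = newf
        if delta < tol:
            converged = True
            break
        if it % 16 == 0:
            # drop pair expansions whose responsibility has collapsed; their
            # future contribution is far below the convergence tolerance
            keep = gamma > 1e-14
            if not keep.all():
                e1, e2, key = e1[keep], e2[keep], key[keep]
    return f, it, converged


def em_haplotype_frequencies(genotypes, hla_pairs, *, tol: float = 1e-8,
                             max_iter: int = 500, prune: float = 1e-9,
                             n_restarts: int = 0, rng=None,
                             max_expansions: int = MAX_EXPANSIONS
                             ) -> HaplotypeTable:
    """Fit extended-haplotype frequencies by EM.

    Parameters
    ----------
    genotypes
        ``(n, k)`` array of alt-allele dosages over a SNP subset, with
        values 0/1/2 and -1 for missing; ``k <= 25``.
    hla_pairs
        Sequence of ``n`` unordered HLA allele pairs (2-tuples of labels).
    tol, max_iter
        Stop when the largest absolute frequency change drops below ``tol``
        or after ``max_iter`` iterations.
    prune
        Frequencies below this are removed after convergence and the table
        renormalised.
    n_restarts
        Additionally run EM from this many random Dirichlet(1) starts and
        keep the solution with the highest log-likelihood (the default
        deterministic uniform start is always included).
    """
    prob, labels = _prepare(genotypes, hla_pairs, max_expansions)
    S = len(prob.support_codes)
    f0 = np.full(S, 1.0 / S)
    best_f, best_it, best_conv = _em_core(prob, f0, tol, max_iter)
    best_ll = _loglik(prob, best_f)
    if n_restarts > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        for _ in range(n_restarts):
            start = rng.dirichlet(np.ones(S))
            f, it, conv = _em_core(prob, start, tol, max_iter)
            ll = _loglik(prob, f)
            if ll > best_ll + 1e-12:
                best_f, best_it, best_conv, best_ll = f, it, conv, ll

    keep = best_f >= prune
    if not keep.any():
        keep = best_f == best_f.max()
    f = best_f[keep]
    f = f / f.sum()
    codes = prob.support_codes[keep]
    A = prob.n_alleles
    pat_codes = codes // A
    allele_idx = codes % A
    patterns = np.zeros((len(codes), prob.k), dtype=np.uint8)
    for j in range(prob.k):
        patterns[:, j] = (pat_codes >> j) & 1
    alleles = np.array([labels[i] for i in allele_idx], dtype=object)
    return HaplotypeTable(patterns, alleles, f, best_ll, best_it, best_conv,
                          prob.n_dropped)
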