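"""Synthetic two-population MHC data with enriched rare haplotypes.

The generator emulates the data situation faced when imputing HLA in a
relatively isolated population: a *generic* population and a *target
isolate* share a pool of common SNP–HLA haplotypes, but the isolate
additionally carries a set of enriched haplotypes that are absent from the
generic population (the analogue of Finnish enriched rare, FER,
haplotypes).  Strong local LD arises naturally because each locus has far
fewer haplotypes than would be possible given its SNP count, so SNP
patterns tag HLA alleles tightly.

Loci are simulated as independent SNP blocks: single-locus imputation
models never use cross-locus information, so cross-locus LD would add cost
without changing any modelled behaviour.  ``recombination_prob`` is kept in
the configuration for interface completeness but is inert under this
independence.  All randomness flows from one integer seed through spawned
``numpy`` generators, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASSICAL_LOCI
from .io import MISSING, GenotypeMatrix, HLATyping

_BASE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T")]  # non-palindromic


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int seed or an already-spawned SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic MHC generator (per-locus unless noted)."""

    n_snps: int = 50
    n_alleles: int = 8
    n_shared_haplotypes: int = 30
    n_enriched_haplotypes: int = 8
    enriched_mass: float = 0.15        # total target-population frequency of enriched haplotypes
    dirichlet_alpha: float = 0.8
    genotype_noise: float = 0.002      # per-site flip probability on emitted genotypes
    recombination_prob: float = 0.01   # inert: loci are independent blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.enriched_mass < 1.0):
            raise ValueError("enriched_mass must lie in (0, 1)")
        for name in ("n_snps", "n_alleles", "n_shared_haplotypes",
                     "n_enriched_haplotypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("genotype_noise", "recombination_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class LocusHaplotypes:
    """Haplotype pool of one locus: SNP allele vectors, HLA labels, frequencies."""

    ids: list[str]
    snp_alleles: np.ndarray     # (H, n_snps) int8 in {0,1}
    hla_labels: list[str]
    freq: np.ndarray            # (H,) sums to 1
    flags: list[str]            # "shared" | "enriched"

    def __post_init__(self) -> None:
        self.snp_alleles = np.asarray(self.snp_alleles, dtype=np.int8)
        self.freq = np.asarray(self.freq, dtype=float)
        if abs(self.freq.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1 within 1e-12")
        if not set(self.hla_labels):
            raise ValueError("empty haplotype pool")


@dataclass
class PopulationModel:
    """Ground-truth haplotype pools for all loci of one population."""

    label: str
    loci: dict[str, LocusHaplotypes]
    snp_ids: dict[str, list[str]]
    snp_positions: dict[str, np.ndarray]
    snp_ref: dict[str, list[str]]
    snp_alt: dict[str, list[str]]

    def allele_frequencies(self, locus: str) -> dict[str, float]:
        pool = self.loci[locus]
        out: dict[str, float] = {}
        for lab, f in zip(pool.hla_labels, pool.freq):
            out[lab] = out.get(lab, 0.0) + float(f)
        return out

    def haplotype_frequency(self, locus: str, hap_id: str) -> float:
        pool = self.loci[locus]
        for hid, f in zip(pool.ids, pool.freq):
            if hid == hap_id:
                return float(f)
        return 0.0

    def enriched_ids(self) -> set[str]:
        return {hid for pool in self.loci.values()
                for hid, fl in zip(pool.ids, pool.flags) if fl == "enriched"}


@dataclass
class Cohort:
    """Sampled individuals: genotypes, truth typing, truth haplotypes."""

    genotypes: GenotypeMatrix
    truth: HLATyping
    truth_haplotypes: pd.DataFrame   # sample, locus, hap1, hap2
    population: str
    locus_snps: dict[str, list[str]] = field(default_factory=dict)


def _allele_name(locus: str, i: int) -> str:
    return f"{locus}*{i + 1:02d}:01"


def simulate_population(cfg: SimulationConfig, seed: int,
                        loci: tuple[str, ...] = CLASSICAL_LOCI,
                        label: str = "generic") -> PopulationModel:
    """Draw the shared haplotype pool of the generic population.

    Per locus: ``n_shared_haplotypes`` haplotypes with uniform-random SNP
    allele vectors; HLA labels assigned so that every one of ``n_alleles``
    labels is carried by at least one haplotype; frequencies drawn from a
    symmetric Dirichlet.  Deterministic given the seed.
    """
    if cfg.n_alleles > cfg.n_shared_haplotypes:
        raise ValueError("n_alleles exceeds n_shared_haplotypes: "
                         "cannot cover every allele")
    root = as_seed_sequence(seed)
    pools: dict[str, LocusHaplotypes] = {}
    snp_ids: dict[str, list[str]] = {}
    snp_pos: dict[str, np.ndarray] = {}
    snp_ref: dict[str, list[str]] = {}
    snp_alt: dict[str, list[str]] = {}
    for k, (locus, child) in enumerate(zip(loci, root.spawn(len(loci)))):
        rng = np.random.default_rng(child)
        H, m = cfg.n_shared_haplotypes, cfg.n_snps
        vectors = rng.integers(0, 2, size=(H, m), dtype=np.int8)
        labels = [_allele_name(locus, i) for i in range(cfg.n_alleles)]
        assignment = labels + [labels[i] for i in
                               rng.integers(0, cfg.n_alleles, size=H - cfg.n_alleles)]
        freq = rng.dirichlet(np.full(H, cfg.dirichlet_alpha))
        freq = freq / freq.sum()
        ids = [f"{locus}:S{i:03d}" for i in range(H)]
        pools[locus] = LocusHaplotypes(ids, vectors, assignment, freq,
                                       ["shared"] * H)
        snp_ids[locus] = [f"rs{locus}_{j:04d}" for j in range(m)]
        snp_pos[locus] = np.arange(m, dtype=np.int64) * 250 + 1_000_000 * (k + 1)
        pair_idx = rng.integers(0, len(_BASE_PAIRS), size=m)
        snp_ref[locus] = [_BASE_PAIRS[i][0] for i in pair_idx]
        snp_alt[locus] = [_BASE_PAIRS[i][1] for i in pair_idx]
    return PopulationModel(label, pools, snp_ids, snp_pos, snp_ref, snp_alt)


def derive_enriched_population(base: PopulationModel, cfg: SimulationConfig,
                               seed: int, label: str = "isolate") -> PopulationModel:
    """Add enriched rare haplotypes to a copy of the base population.

    Per locus, ``n_enriched_haplotypes`` novel haplotypes are created by
    mutating a random shared haplotype at 10-30% of its SNP sites, with an
    HLA label drawn from the existing allele set.  They receive total
    frequency ``enriched_mass`` (split by a Dirichlet draw); shared
    haplotype frequencies are rescaled by ``1 - enriched_mass``.  The base
    population carries none of the enriched haplotypes (frequency 0).
    """
    root = as_seed_sequence(seed)
    pools: dict[str, LocusHaplotypes] = {}
    for locus, child in zip(base.loci, root.spawn(len(base.loci))):
        rng = np.random.default_rng(child)
        pool = base.loci[locus]
        H, m = pool.snp_alleles.shape
        E = cfg.n_enriched_haplotypes
        vectors = []
        labels = []
        allele_set = sorted(set(pool.hla_labels))
        for e in range(E):
            parent = int(rng.integers(0, H))
            rate = rng.uniform(0.10, 0.30)
            n_mut = max(1, int(round(rate * m)))
            sites = rng.choice(m, size=n_mut, replace=False)
            vec = pool.snp_alleles[parent].copy()
            vec[sites] = 1 - vec[sites]
            vectors.append(vec)
            labels.append(allele_set[int(rng.integers(0, len(allele_set)))])
        efreq = rng.dirichlet(np.full(E, cfg.dirichlet_alpha)) * cfg.enriched_mass
        sfreq = pool.freq * (1.0 - cfg.enriched_mass)
        freq = np.concatenate([sfreq, efreq])
        freq = freq / freq.sum()
        ids = list(pool.ids) + [f"{locus}:E{e:03d}" for e in range(E)]
        pools[locus] = LocusHaplotypes(
            ids, np.vstack([pool.snp_alleles, np.array(vectors, dtype=np.int8)]),
            list(pool.hla_labels) + labels, freq,
            list(pool.flags) + ["enriched"] * E)
    return PopulationModel(label, pools, dict(base.snp_ids),
                           {k: v.copy() for k, v in base.snp_positions.items()},
                           dict(base.snp_ref), dict(base.snp_alt))


def sample_cohort(pop: PopulationModel, n: int, cfg: SimulationConfig,
                  seed: int, sample_prefix: str = "S") -> Cohort:
    """Draw ``n`` individuals from a population.

    Per sample and locus, two haplotypes are drawn i.i.d. from the locus
    frequency table; the genotype is their allele sum, after which each
    site is flipped with probability ``genotype_noise`` (0->1, 2->1, and
    1 -> 0 or 2 with equal odds).  Truth typing and truth haplotype IDs are
    recorded before noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = as_seed_sequence(seed)
    samples = [f"{sample_prefix}{i:05d}" for i in range(n)]
    truth = HLATyping()
    hap_rows = []
    blocks = []
    all_ids: list[str] = []
    all_pos: list[np.ndarray] = []
    all_ref: list[str] = []
    all_alt: list[str] = []
    locus_snps: dict[str, list[str]] = {}
    for locus, child in zip(pop.loci, root.spawn(len(pop.loci))):
        rng = np.random.default_rng(child)
        pool = pop.loci[locus]
        H = len(pool.ids)
        draws = rng.choice(H, size=(n, 2), p=pool.freq)
        dosage = (pool.snp_alleles[draws[:, 0]]
                  + pool.snp_alleles[draws[:, 1]]).astype(np.int8)
        if cfg.genotype_noise > 0:
            flip = rng.random(dosage.shape) < cfg.genotype_noise
            up = rng.random(dosage.shape) < 0.5  # direction for het sites
            noisy = dosage.copy()
            noisy[flip & (dosage == 0)] = 1
            noisy[flip & (dosage == 2)] = 1
            het = flip & (dosage == 1)
            noisy[het & up] = 2
            noisy[het & ~up] = 0
            dosage = noisy
        for i, s in enumerate(samples):
            h1, h2 = int(draws[i, 0]), int(draws[i, 1])
            truth.set(s, locus, pool.hla_labels[h1], pool.hla_labels[h2])
            hap_rows.append((s, locus, pool.ids[h1], pool.ids[h2]))
        blocks.append(dosage)
        all_ids.extend(pop.snp_ids[locus])
        all_pos.append(pop.snp_positions[locus])
        all_ref.extend(pop.snp_ref[locus])
        all_alt.extend(pop.snp_alt[locus])
        locus_snps[locus] = list(pop.snp_ids[locus])
    g = GenotypeMatrix(samples, all_ids, np.concatenate(all_pos),
                       all_ref, all_alt, np.hstack(blocks))
    hap_df = pd.DataFrame(hap_rows, columns=["sample", "locus", "hap1", "hap2"])
    return Cohort(g, truth, hap_df, pop.label, locus_snps)


def simulate_phenotypes(truth: HLATyping, effects: dict[str, float],
                        covar_effects: dict[str, float] | None = None,
                        prevalence_intercept: float = -2.1972245773362196,  # logit(0.1)
                        n_pcs: int = 10, seed: int = 0) -> pd.DataFrame:
    """Draw case/control status from planted HLA allele effects.

    Status is Bernoulli(logistic(intercept + sum allele_dosage * logOR +
    covariate terms)).  Covariates: age ~ N(55, 10), sex ~ Bernoulli(0.5),
    BMI ~ N(27, 4), PCs ~ N(0, 1).  Covariate effects (``covar_effects``,
    keyed by column name) apply to mean-centred covariates so that the
    intercept keeps its logit-prevalence interpretation.
    """
    rng = np.random.default_rng(as_seed_sequence(seed))
    samples = truth.samples()
    n = len(samples)
    known = {a for s in samples for pair in truth.calls[s].values() for a in pair}
    for allele in effects:
        if allele not in known:
            raise ValueError(f"effect references allele {allele!r} "
                             "absent from the truth typing")
    age = rng.normal(55.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    bmi = rng.normal(27.0, 4.0, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, n_pcs))
    lin = np.full(n, prevalence_intercept)
    for i, s in enumerate(samples):
        for pair in truth.calls[s].values():
            for a in pair:
                lor = effects.get(a)
                if lor:
                    lin[i] += lor
    cov = {"age": age, "sex": sex, "bmi": bmi}
    for k in range(n_pcs):
        cov[f"PC{k + 1}"] = pcs[:, k]
    if covar_effects:
        for name, beta in covar_effects.items():
            if name not in cov:
                raise ValueError(f"unknown covariate {name!r}")
            x = cov[name]
            lin += beta * (x - x.mean())
    p = 1.0 / (1.0 + np.exp(-lin))
    status = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"sample": samples, "status": status,
                       "age": age, "sex": sex, "bmi": bmi})
    for k in range(n_pcs):
        df[f"PC{k + 1}"] = pcs[:, k]
    return df
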