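"""Run configuration for the imputation pipeline.

A single :class:`RunConfig` travels through training, imputation and all
downstream analyses so that a run is fully described by one object (and one
YAML file).  Defaults follow common practice for SNP-based HLA imputation:
seven classical loci, 100 classifiers per locus, and a genome-wide-style
fixed significance threshold of 5e-5 for allele association scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: The seven classical HLA loci imputed by default.
CLASSICAL_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPB1")

#: Default posterior-probability threshold grid for retention sweeps.
DEFAULT_PP_GRID = tuple(round(0.05 * i, 2) for i in range(20))  # 0.00 .. 0.95


@dataclass
class RunConfig:
    """Parameters controlling a full imputation + evaluation run.

    Parameters
    ----------
    loci
        Ordered HLA locus names to model.
    n_classifiers
        Number of bagged classifiers per locus model.
    pp_threshold_grid
        Strictly ascending posterior-probability thresholds in [0, 1] used
        by retention sweeps and frequency/association sensitivity analyses.
    n_bootstrap
        Bootstrap replicates for error distributions.
    n_permutations
        Replicates for permutation tests on paired error counts.
    alpha_assoc
        Fixed significance threshold for the association scan.
    n_pcs
        Number of genetic principal components used as covariates.
    seed
        Master seed; every stochastic stage derives its stream from it.
    subset_size
        SNPs per classifier before refinement; ``None`` means
        ``ceil(sqrt(n_candidate_snps))``.
    greedy_moves
        Maximum grow/swap refinement moves per classifier, each accepted
        only if it raises out-of-bag accuracy.
    max_subset
        Hard cap on classifier SNP subset size (haplotype-pattern
        enumeration bound).
    em_tol, em_max_iter
        Convergence tolerance (max absolute frequency change) and iteration
        cap for the haplotype-frequency EM.
    freq_prune
        Haplotype frequencies below this are pruned after EM, then the
        table is renormalised.
    classifier_weighting
        ``"oob"`` weights classifier posteriors by out-of-bag accuracy;
        ``"uniform"`` averages them equally.
    assoc_freq_floor
        Minimum imputed allele frequency for inclusion in the association
        scan (guards against separation artifacts).
    assoc_dosage_mode
        ``"best_guess"`` (0/1/2 from the called pair) or ``"expected"``
        (posterior-expected dosage).
    """

    loci: Sequence[str] = CLASSICAL_LOCI
    n_classifiers: int = 100
    pp_threshold_grid: Sequence[float] = DEFAULT_PP_GRID
    n_bootstrap: int = 100
    n_permutations: int = 1000
    alpha_assoc: float = 5e-5
    n_pcs: int = 10
    seed: int = 0
    subset_size: int | None = None
    greedy_moves: int = 5
    max_subset: int = 25
    em_tol: float = 1e-8
    em_max_iter: int = 500
    freq_prune: float = 1e-9
    classifier_weighting: str = "oob"
    assoc_freq_floor: float = 0.005
    assoc_dosage_mode: str = "best_guess"

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.pp_threshold_grid = tuple(float(t) for t in self.pp_threshold_grid)
        if not self.loci:
            raise ValueError("at least one locus is required")
        grid = self.pp_threshold_grid
        if any(t < 0.0 or t > 1.0 for t in grid):
            raise ValueError("pp_threshold_grid values must lie in [0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("pp_threshold_grid must be strictly ascending")
        for name in ("n_classifiers", "n_bootstrap", "n_permutations", "n_pcs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.alpha_assoc < 1.0):
            raise ValueError("alpha_assoc must lie in (0, 1)")
        if self.classifier_weighting not in ("oob", "uniform"):
            raise ValueError("classifier_weighting must be 'oob' or 'uniform'")
        if self.assoc_dosage_mode not in ("best_guess", "expected"):
            raise ValueError("assoc_dosage_mode must be 'best_guess' or 'expected'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loci"] = list(self.loci)
        d["pp_threshold_grid"] = list(self.pp_threshold_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
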