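"""End-to-end study workflows on synthetic data.

The central design mirrors a population-specific imputation study: train
one reference panel on the target isolate (which carries enriched rare
haplotypes) and one on the generic population, impute an independent test
cohort drawn from the isolate with both, and compare their error
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import ErrorTable, count_errors
from .model import HLAImputationModel, HLAImputationResults, ImputationSet
from .simulate import (Cohort, PopulationModel, SimulationConfig,
                       derive_enriched_population, sample_cohort,
                       simulate_population)


@dataclass
class PanelComparison:
    """Everything produced by one matched-vs-generic panel experiment."""

    generic_pop: PopulationModel
    isolate_pop: PopulationModel
    test_cohort: Cohort
    matched: HLAImputationResults      # panel trained on the isolate
    generic: HLAImputationResults      # panel trained on the generic population
    calls_matched: ImputationSet
    calls_generic: ImputationSet
    errors_matched: ErrorTable
    errors_generic: ErrorTable

    @property
    def enriched_ids(self) -> set[str]:
        return self.isolate_pop.enriched_ids()


def panel_comparison(seed: int, sim_cfg: SimulationConfig | None = None,
                     run_cfg: RunConfig | None = None, n_ref: int = 800,
                     n_test: int = 200, loci: tuple[str, ...] | None = None,
                     full_posteriors: bool = False) -> PanelComparison:
    """Run one seeded matched-vs-generic reference panel experiment.

    Simulates the two populations, samples a reference cohort of ``n_ref``
    from each and a test cohort of ``n_test`` from the isolate, trains both
    panels, imputes the test cohort with each, and scores errors against
    the truth typing.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    run_cfg = run_cfg or RunConfig()
    loci = tuple(loci) if loci is not None else tuple(run_cfg.loci)
    root = np.random.SeedSequence(seed)
    s_pop, s_enr, s_ref_g, s_ref_m, s_test, s_fit_g, s_fit_m = root.spawn(7)

    generic_pop = simulate_population(sim_cfg, s_pop, loci=loci)
    isolate_pop = derive_enriched_population(generic_pop, sim_cfg, s_enr)

    ref_generic = sample_cohort(generic_pop, n_ref, sim_cfg, s_ref_g,
                                sample_prefix="G")
    ref_isolate = sample_cohort(isolate_pop, n_ref, sim_cfg, s_ref_m,
                                sample_prefix="F")
    test = sample_cohort(isolate_pop, n_test, sim_cfg, s_test,
                         sample_prefix="T")

    matched = HLAImputationModel.from_cohort(ref_isolate, run_cfg).fit(
        seed=s_fit_m, loci=loci)
    generic = HLAImputationModel.from_cohort(ref_generic, run_cfg).fit(
        seed=s_fit_g, loci=loci)

    calls_m = matched.impute(test.genotypes, full_posteriors=full_posteriors)
    calls_g = generic.impute(test.genotypes, full_posteriors=full_posteriors)
    err_m = count_errors(test.truth, calls_m.calls, panel="matched")
    err_g = count_errors(test.truth, calls_g.calls, panel="generic")
    return PanelComparison(generic_pop, isolate_pop, test, matched, generic,
                           calls_m, calls_g, err_m, err_g)


def exchangeable_error_tables(seed: int, n_samples: int = 100,
                              loci: tuple[str, ...] = ("A", "B", "C"),
                              error_prob: float = 0.05
                              ) -> tuple[ErrorTable, ErrorTable]:
    """Two error tables drawn i.i.d. from one error process (a true null).

    Emulates two re-seeded runs of the same panel on the same samples:
    per sample and locus, each table independently draws an error count
    (0 w.p. 1-error_prob, else 1 or 2) and a posterior that is lower for
    erroneous calls.  Used to calibrate the permutation tests.
    """
    rng = np.random.default_rng(seed)

    def one() -> ErrorTable:
        rows = []
        for i in range(n_samples):
            for locus in loci:
                u = rng.random()
                err = 0 if u > error_prob else (1 if u > error_prob / 4 else 2)
                post = rng.beta(8, 1) if err == 0 else rng.beta(2, 2)
                rows.append((f"S{i:04d}", locus, err, post))
        return ErrorTable(pd.DataFrame(
            rows, columns=["sample", "locus", "errors", "posterior"]))

    return one(), one()
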