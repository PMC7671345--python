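"""Shared fixtures: small trained models and the full panel-comparison runs."""

import numpy as np
import pytest

from hlabag import RunConfig, SimulationConfig
from hlabag.workflows import panel_comparison


@pytest.fixture(scope="session")
def small_run():
    """A small two-locus matched-panel run for unit-level checks.

    Reference of 300 isolate samples, 8 classifiers per locus, 60-sample
    test cohort; returns the PanelComparison bundle.
    """
    return panel_comparison(seed=424242,
                            run_cfg=RunConfig(n_classifiers=8),
                            n_ref=300, n_test=60, loci=("A", "B"),
                            full_posteriors=True)


@pytest.fixture(scope="session")
def study_runs():
    """Twenty seeded replicates of the matched-vs-generic panel study.

    Study conditions: simulation defaults (7 loci, 50 SNPs and 8 alleles
    per locus, enriched mass 0.15), 800 reference samples per population,
    200 isolate test samples, 25 classifiers per locus.
    """
    cfg = RunConfig(n_classifiers=25)
    sim = SimulationConfig()
    return [panel_comparison(seed=seed, sim_cfg=sim, run_cfg=cfg,
                             n_ref=800, n_test=200)
            for seed in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
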