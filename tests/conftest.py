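"""Shared fixtures: synthetic cohorts at two scales.

Cohorts are generated once per session into pytest's tmp tree; nothing is
read from or written to the repository.
"""

from __future__ import annotations

import pytest

from splicedelta.pipeline import config_from_cohort, run_pipeline
from splicedelta.simulate import ReporterLocusSpec, SpliceScenario, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Quick cohort with every event type planted plus the reporter locus."""
    scenario = SpliceScenario(
        n_genes=30,
        exons_per_gene=(2, 4),
        expression=250.0,
        n_ir=4,
        n_mes=2,
        n_es=2,
        n_alt_acceptor=3,
        n_alt_donor=1,
        n_deg_up=3,
        n_deg_down=2,
        reporter=ReporterLocusSpec(fragments_per_replicate=1000),
        seed=123,
    )
    return simulate_cohort(scenario, tmp_path_factory.mktemp("small_cohort"))


@pytest.fixture(scope="session")
def small_result(small_cohort, tmp_path_factory):
    config = config_from_cohort(small_cohort, tmp_path_factory.mktemp("small_out"))
    return run_pipeline(config)


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory):
    """Both conditions drawn from identical parameters: 500 introns, 3v3,
    ~50x exon coverage."""
    scenario = SpliceScenario(
        n_genes=500,
        exons_per_gene=(2, 2),
        seed=2024,  # defaults give ~50x mean exon depth at 100 nt reads
    )
    return simulate_cohort(scenario, tmp_path_factory.mktemp("null_cohort"))


@pytest.fixture(scope="session")
def null_result(null_cohort, tmp_path_factory):
    config = config_from_cohort(null_cohort, tmp_path_factory.mktemp("null_out"))
    return run_pipeline(config, stages=("deg", "splice"))


@pytest.fixture(scope="session")
def recovery_cohort(tmp_path_factory):
    """5x retention planted in 50 of 500 introns at ~50x coverage."""
    scenario = SpliceScenario(
        n_genes=500,
        exons_per_gene=(2, 2),
        n_ir=50,
        ir_fold=5.0,
        seed=77,
    )
    return simulate_cohort(scenario, tmp_path_factory.mktemp("recovery_cohort"))


@pytest.fixture(scope="session")
def recovery_result(recovery_cohort, tmp_path_factory):
    config = config_from_cohort(
        recovery_cohort, tmp_path_factory.mktemp("recovery_out")
    )
    return run_pipeline(config, stages=("splice",))
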