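import numpy as np
import pandas as pd
import pytest

from qtlallele.simulate import (
    SimConfig,
    assign_qtl_effects,
    markers_from_true_blocks,
    simulate_drought_trial,
    simulate_founder_genotypes,
    simulate_study,
)


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_accessions=120,
        n_chromosomes=3,
        snps_per_chromosome=40,
        n_qtl=5,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def study():
    """One modest synthetic study shared across read-only tests."""
    cfg = small_config()
    panel, models, trial = simulate_study(cfg)
    return cfg, panel, models, trial


@pytest.fixture(scope="session")
def panel(study):
    return study[1]


@pytest.fixture(scope="session")
def true_markers(panel):
    return markers_from_true_blocks(panel)


@pytest.fixture(scope="session")
def fitted_model(study, true_markers):
    """A stage-1 + stage-2 fit of MPW-like data on the small panel."""
    from qtlallele.association import stage1_scan, stage2_stepwise
    from qtlallele.phenotype import anova_heritability, membership_index, relative_trait
    from qtlallele.similarity import genetic_similarity, top_eigenvectors

    cfg, panel, models, trial = study
    X = relative_trait(trial.data, "plant_weight")
    res = membership_index(X, trial.tolerant_checks, trial.sensitive_checks)
    h2 = anova_heritability(res.M).h2
    basis = top_eigenvectors(genetic_similarity(true_markers), 5)
    scan = stage1_scan(true_markers, res.accession_mean, basis)
    model = stage2_stepwise(
        true_markers, scan.preselected, res.accession_mean, basis, h2_cap=h2
    )
    return model, res.accession_mean, basis, h2
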