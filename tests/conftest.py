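import warnings

import pytest

from twaskit.config import SimConfig
from twaskit.simulate import (simulate_feature_correlation,
                              simulate_gene_annotation,
                              simulate_twas_sumstats)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # empty weight sets and dropped constant genes are expected events in
    # small fixtures; they stay warnings in production use
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="empty weight set")
        warnings.filterwarnings("ignore", message="dropping .*zero-variance")
        warnings.filterwarnings("ignore", message="dropping .*constant genes")
        yield


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast study: 200 genes, 2 panels, 150+150 samples per platform."""
    return SimConfig(n_genes=200, n_panels=2, panel_strata=("blood", "brain"),
                     n_signal_genes=15, n_cases=150, n_controls=150,
                     n_drugs=60, n_enriched_drugs=5, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    annotation = simulate_gene_annotation(small_config)
    twas, truth = simulate_twas_sumstats(small_config, annotation)
    corr = simulate_feature_correlation(small_config, annotation)
    return small_config, annotation, twas, truth, corr
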