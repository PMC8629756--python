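import pytest

from rarescreen.config import ThresholdConfig
from rarescreen.simulate import SimConfig, default_truths, generate_cohorts


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully-featured two-cohort simulation shared across tests.

    Background prevalence of the target phecodes is raised so every target
    clears the 30-case filter at this reduced scale.
    """
    cfg = SimConfig(seed=7, cohort_sizes=(4000, 1500))
    truths = default_truths(
        n_null_genes=8,
        n_causal_genes=2,
        causal_penetrance=(0.8, 0.7),
        causal_carrier_freq=(0.004, 0.004),
        target_background_prevalence=0.03,
    )
    cohorts, pmap, truth_tables = generate_cohorts(cfg, truths)
    return {
        "config": cfg,
        "truths": truths,
        "cohorts": cohorts,
        "pmap": pmap,
        "truth_tables": truth_tables,
    }
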