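import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fibersynergy import synergy, synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ferm_default():
    """Paper-sized cohort with default injected synergy (seeded)."""
    table, truth = synthetic.generate_fermentation_table(synthetic.FermGenConfig(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def ferm_noise_free():
    """Zero-noise cohort: synergy is exactly the injected delta."""
    cfg = synthetic.FermGenConfig(seed=12, noise_sd=0.0)
    return synthetic.generate_fermentation_table(cfg)


@pytest.fixture(scope="session")
def synergy_table(ferm_default):
    table, _ = ferm_default
    return synergy.apply_filters(synergy.compute_synergy(table))


@pytest.fixture(scope="session")
def taxa_default():
    cfg = synthetic.TaxaGenConfig(seed=13, n_taxa=30, n_samples_per_group=15,
                                  enriched_taxa={"taxon_005": 4.0})
    return synthetic.generate_taxa_counts(cfg)


@pytest.fixture()
def tiny_ferm():
    """Hand-built two-donor table with known mixture/fiber values."""
    rows = []
    fibers = {"pectin": 8.0, "beta_glucan": 4.0, "fos": 6.0, "arabinoxylan": 2.0}
    for donor, mix in (("d1", 7.5), ("d2", 5.0)):
        for fiber, value in fibers.items():
            rows.append((donor, "HC", fiber, "acetate", value))
        rows.append((donor, "HC", "mixture", "acetate", mix))
    return pd.DataFrame(
        rows, columns=["donor_id", "condition", "substrate", "scfa_type", "concentration_mM"]
    )
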