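"""Shared fixtures: synthetic corpora and trained surrogate bundles.

The heavyweight model bundles are session-scoped so the fidelity,
simulation and optimizer tests share one training run per condition.
"""

import numpy as np
import pytest
from hypothesis import settings

import phycolight as pl

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pbr_bundle_clean():
    """Noise-free 20x20 photobioreactor benchmark bundle."""
    return pl.build_default_models("pbr", seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def pbr_bundle():
    """Photobioreactor bundle at the default camera noise (3 gray sd)."""
    return pl.build_default_models("pbr", seed=1)


@pytest.fixture(scope="session")
def pond_bundle():
    """Open-pond bundle (14x14 condition grid keeps it light)."""
    return pl.build_default_models("pond", seed=1, n_intensities=14,
                                   n_concentrations=14)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small, fast bundle for plumbing-level tests."""
    return pl.build_default_models(
        "pbr", seed=3, n_intensities=8, n_concentrations=8,
        grm_initial_ods=(0.5, 1.5, 3.0),
    )


@pytest.fixture(scope="session")
def pbr_conditions():
    geometry, optics, truth = pl.pbr_preset()
    return geometry, optics, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
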