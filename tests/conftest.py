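import numpy as np
import pytest

from amcarbon import (GeneratorConfig, KineticModelSpec, MCMCConfig,
                      build_design, fit_hierarchical_model, generate_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """One default three-group cohort, shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def quick_mcmc():
    """Shortened chains for unit tests that do not assert diagnostics."""
    return MCMCConfig(n_burn=900, n_steps=600, thin=4, seed=3)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Group-effect fit of the default cohort at full chain length."""
    spec = KineticModelSpec()
    design = build_design(default_cohort, spec)
    return fit_hierarchical_model(design, spec, MCMCConfig(seed=5))


@pytest.fixture(scope="session")
def pooled_fit(default_cohort):
    spec = KineticModelSpec(group_effect=False)
    design = build_design(default_cohort, spec)
    return fit_hierarchical_model(design, spec, MCMCConfig(seed=5))


def brute_force_disk_pixels(shape, center, radius):
    """Independent pixel-enumeration oracle for circular blobs."""
    count = 0
    r0, c0 = center
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - r0) ** 2 + (c - c0) ** 2 <= radius ** 2:
                count += 1
    return count


@pytest.fixture(scope="session")
def disk_oracle():
    return brute_force_disk_pixels
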