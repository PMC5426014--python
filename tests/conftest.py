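import pytest

from neurocp import (DeltaGridSpec, SimCohortSpec, fa_pattern_spec,
                     make_delta_grid, simulate_cohort, simulate_region)


@pytest.fixture(scope="session")
def cohort():
    """Default 43+43 synthetic cohort."""
    return simulate_cohort(SimCohortSpec(seed=42))


@pytest.fixture(scope="session")
def grid(cohort):
    return make_delta_grid(cohort, DeltaGridSpec())


@pytest.fixture(scope="session")
def noisy_region(cohort):
    """A clearly detectable rise-then-plateau FA region (|a2|/sigma = 4)."""
    spec = fa_pattern_spec(1, "rise_plateau", delta_true=30.0, noise_sd=0.002)
    return simulate_region(cohort, spec, seed=7)


def region_values(cohort, pattern="rise_plateau", delta=30.0, noise_sd=0.0,
                  seed=0, region_id=1):
    spec = fa_pattern_spec(region_id, pattern, delta_true=delta,
                           noise_sd=noise_sd)
    return simulate_region(cohort, spec, seed=seed).values
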