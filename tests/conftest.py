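import pytest

from mutaspec.pipeline import run_cohort
from mutaspec.synthetic_data import (
    SimulationConfig,
    carbon_profile,
    gamma_profile,
    simulate_mutant_lines,
)

#: per-line expected-count multiplier and cohort size for desk-scale tests
TEST_SCALE = 0.08
TEST_LINES = 4


@pytest.fixture(scope="session")
def noisy_cohort():
    """Two small groups with every planted noise process switched on."""
    config = SimulationConfig(
        seed=11, n_ck_shared=10, n_crossline_shared=8, n_low_quality=3
    )
    return simulate_mutant_lines(
        config,
        [carbon_profile(TEST_SCALE, TEST_LINES), gamma_profile(TEST_SCALE, TEST_LINES)],
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no background, no low-quality calls, no scaffolds."""
    config = SimulationConfig(
        seed=12,
        n_ck_shared=0,
        n_ck_private=0,
        n_crossline_shared=0,
        n_low_quality=0,
        scaffold_fraction=0.0,
    )
    return simulate_mutant_lines(
        config,
        [carbon_profile(TEST_SCALE, TEST_LINES), gamma_profile(TEST_SCALE, TEST_LINES)],
    )


@pytest.fixture(scope="session")
def noisy_line_sets(noisy_cohort):
    return run_cohort(
        noisy_cohort.lines,
        noisy_cohort.controls,
        chromosome_names=set(noisy_cohort.config.chromosomes),
    )
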