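import warnings

import pytest

from pcfidelity.synthetic import SimConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down cohort for fast structural tests."""
    base = dict(
        seed=seed,
        n_primary=60,
        n_met_per_site={"bone": 12, "liver": 10, "lymph_node": 10},
        n_cell_lines=6,
        n_genes=400,
        n_diff_genes=10,
        n_high_genes=5,
        n_hotspots=4,
        n_program_genes=30,
        n_cells_per_sample=3,
        n_normal_cells_per_type=10,
        n_peaks=500,
        n_cnv_genes=60,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the standard study conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(small_config(seed=0))
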