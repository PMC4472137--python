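import numpy as np
import pytest

import bonecycle as bc


@pytest.fixture(scope="session")
def default_grid():
    return bc.ParameterGrid()


@pytest.fixture(scope="session")
def grid_matrix(default_grid):
    from bonecycle.gridfit import grid_arrays

    return grid_arrays(default_grid)


@pytest.fixture(scope="session")
def best_fit_trajectory():
    return bc.simulate_plenary(bc.WEEKLY_TERIPARATIDE_FIT, 18)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Small synthetic cohort at the reference parameter set, fixed seed."""
    return bc.generate_cohort(bc.CohortConfig(n_subjects=50, seed=7))


def random_valid_params(rng, override=False):
    """Draw a valid plenary parameter set away from the boundaries."""
    r_R = rng.uniform(0.02, 0.5)
    r_F = rng.uniform(r_R + 0.01, 0.9) if not override else rng.uniform(0.02, 0.9)
    return bc.PlenaryParams(
        r_R=r_R,
        r_F=r_F,
        f_MAT=rng.uniform(0.01, 0.5),
        f_BMD=rng.uniform(0.05, 0.95),
        k=rng.uniform(0.05, 0.95),
        override=override,
    )
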