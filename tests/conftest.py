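import numpy as np
import pandas as pd
import pytest

from numerosym import EXP1, EXP2, fit_all_cells, simulate_experiment
from numerosym.cohort import EXP2_BIAS_PROFILE, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def exp1_runs():
    """Three independent Exp-1 cohorts (19 observers each) simulated and fitted.

    Generative conditions: Wf0 = 0.25, N' = 100, alpha = 0.5, vertical-symmetry
    bias -7% (estimation) / -3% (density), random unbiased; the design's full
    2 x 50 trials per cell.  Shared by the parameter- and bias-recovery tests.
    """
    runs = []
    for seed in (0, 1, 2):
        spec = CohortSpec(n_participants=19, master_seed=seed)
        cohort = generate_cohort(spec, standards=EXP1.standards)
        trials = simulate_experiment(cohort, EXP1, master_seed=seed)
        runs.append((cohort, trials, fit_all_cells(trials)))
    return runs


@pytest.fixture(scope="session")
def exp2_runs():
    """Two Exp-2 cohorts (16 observers) with the three-condition bias profile."""
    runs = []
    for seed in (0, 1):
        spec = CohortSpec(
            n_participants=16, bias_profile=dict(EXP2_BIAS_PROFILE), master_seed=seed
        )
        cohort = generate_cohort(spec, standards=EXP2.standards)
        trials = simulate_experiment(cohort, EXP2, master_seed=seed)
        runs.append((cohort, trials, fit_all_cells(trials)))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
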