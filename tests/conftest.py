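"""Shared fixtures: canonical datasets and session-scoped simulation experiments.

The two Monte-Carlo experiments are expensive relative to everything else,
so they run once per session and several tests read different properties
off the same result (abundance bias, interval coverage, coefficient bias,
variance calibration, AICc ranking frequencies).
"""

import numpy as np
import pytest

from dosabund import (
    DetectionModelSpec,
    GroupRecord,
    SimulationConfig,
    SurveyDataset,
    recovery_experiment,
)

RECOVERY_SEED = 20200211
HET_SEED = 20190325
N_REPS = 200

#: no-heterogeneity study condition: 200 groups, 10% collared, both observers
#: at p = 0.5, skewed group sizes (generator defaults)
NO_HET_CONFIG = SimulationConfig(seed=0)

#: strong-heterogeneity study condition: group-level logit random effect
#: SD 1.5 shared by both observers, otherwise as above
HET_CONFIG = SimulationConfig(sigma_het=1.5, seed=0)

OBSERVER_SPEC = DetectionModelSpec(label="observer")
RECAPTURE_SPEC = DetectionModelSpec(recapture_effect=True, label="observer + recapture")


@pytest.fixture(scope="session")
def recovery_no_het():
    """Simulate/fit/average 200 no-heterogeneity surveys with the matching spec."""
    return recovery_experiment(NO_HET_CONFIG, [OBSERVER_SPEC], n_reps=N_REPS,
                               seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_het():
    """200 heterogeneous surveys fitted with observer-only vs observer+recapture."""
    return recovery_experiment(HET_CONFIG, [OBSERVER_SPEC, RECAPTURE_SPEC],
                               n_reps=N_REPS, seed=HET_SEED)


def lincoln_petersen_dataset() -> SurveyDataset:
    """12 uncollared singleton groups: (1,1) x8, (1,0) x2, (0,1) x2.

    Closed form: p1 = n11/(n11+n01) = 0.8, p2 = n11/(n11+n10) = 0.8,
    N = 12 / (1 - 0.2 * 0.2) = 12.5.
    """
    histories = [(1, 1)] * 8 + [(1, 0)] * 2 + [(0, 1)] * 2
    records = [
        GroupRecord(group_id=f"lp{i:02d}", detected_obs1=a, detected_obs2=b, size_best=1)
        for i, (a, b) in enumerate(histories)
    ]
    return SurveyDataset(records, survey_label="lincoln-petersen")


@pytest.fixture
def lp_dataset() -> SurveyDataset:
    return lincoln_petersen_dataset()
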