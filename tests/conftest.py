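"""Shared fixtures: synthetic cohorts at a few sizes, reused across modules.

Everything is generated in memory from fixed seeds; no data files.
"""

import numpy as np
import pytest

from prsbench import SimulationConfig, align, simulate_cohort
from prsbench.simulate import DiseaseSpec, MortalitySpec


@pytest.fixture(scope="session")
def sim_carrier_rich():
    """Larger EUR cohort with a strong PRS effect and common 'carriers',
    sized so carrier and band curves are well populated."""
    cfg = SimulationConfig(
        seed=23,
        n_per_ancestry={"EUR": 30000},
        diseases={
            "CAD": DiseaseSpec(
                name="CAD",
                log_hr_per_sd=0.5,
                sex_log_hr=0.4,
                carrier_freq=0.01,
                carrier_log_hr=float(np.log(3.0)),
                treatment=True,
            )
        },
        quants={},
        score_correlation={},
        mortality=MortalitySpec(log_hr_per_sd={}),
    )
    sim = simulate_cohort(cfg)
    frame = align(sim.cohort, sim.scores, sim.diseases["CAD"])
    return cfg, sim, frame
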