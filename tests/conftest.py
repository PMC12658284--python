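import numpy as np
import pytest

from ictalsync.calibration import reduced_sim_config
from ictalsync.simulate import CoupledPair, simulate_cohort


@pytest.fixture(scope="session")
def effect_cohort():
    """Small cohort with a terminally boosted C3–C4 coupling."""
    cfg = reduced_sim_config(
        n_seizures=8, terminal_boost=3.0, coupled_pairs=(CoupledPair("C3", "C4"),), seed=3
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_table(effect_cohort):
    from ictalsync.pipeline import build_synchrony_table

    recording, truth = effect_cohort
    return build_synchrony_table(recording, truth.markers, patient_id="sim")


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
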