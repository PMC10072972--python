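import numpy as np
import pytest

import gaitconn as gc
from gaitconn.synth import recovery_coupling_profiles


@pytest.fixture(scope="session")
def recovery_session():
    """Simulated session with the Latin-square recovery coupling layout.

    SNR >= 10 (signal amplitude ~1, noise SD 0.2), fixed seed; returns the
    phase-collapsed PLI, its condition averages and the ground truth.
    """
    cfg = gc.SimConfig(
        n_epochs_per_condition=10,
        coupling_profiles=recovery_coupling_profiles(),
        seed=0,
    )
    rec, events, truth = gc.simulate_recording(cfg)
    epochs = gc.preprocess_recording(rec, events)
    tensor = gc.sliding_pli(epochs)
    phase_conn = gc.collapse_phases(tensor)
    avg, conds = gc.condition_average(phase_conn)
    return {
        "epochs": epochs,
        "tensor": tensor,
        "phase_conn": phase_conn,
        "avg": avg,
        "conds": conds,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def classification_session():
    """Session with the default condition-differentiated coupling profile.

    Condition differences live only in the two late walking sub-phases,
    so phase-resolved features should separate conditions while the
    preparation phase alone should not.
    """
    cfg = gc.SimConfig(n_epochs_per_condition=30, seed=0)
    rec, events, truth = gc.simulate_recording(cfg)
    epochs = gc.preprocess_recording(rec, events)
    tensor = gc.sliding_pli(epochs)
    phase_conn = gc.collapse_phases(tensor)
    return {"epochs": epochs, "tensor": tensor, "phase_conn": phase_conn,
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
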