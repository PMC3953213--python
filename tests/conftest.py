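import numpy as np
import pandas as pd
import pytest

from lrpddm.ddm import DDMParams
from lrpddm.lrp import EEGEpochs


@pytest.fixture(scope="session")
def low_coh_params() -> DDMParams:
    """Published low-coherence fit with an unbiased starting point."""
    return DDMParams.unbiased(0.060, 0.151, 0.435)


def make_epochs(data: np.ndarray, sfreq: float = 250.0,
                resp_ms=None, hand=None, condition="c",
                correct=None, tmin_ms: float = -200.0) -> EEGEpochs:
    """Small EEGEpochs builder for hand-constructed fixtures."""
    n = data.shape[0]
    n_samp = data.shape[2]
    t_end = tmin_ms + (n_samp - 1) * 1000.0 / sfreq
    trials = pd.DataFrame({
        "stim_ms": np.zeros(n),
        "resp_ms": (np.full(n, min(400.0, t_end - 1))
                    if resp_ms is None else np.asarray(resp_ms, float)),
        "hand": np.full(n, "left") if hand is None else np.asarray(hand),
        "condition": np.full(n, condition),
        "correct": np.ones(n, bool) if correct is None else np.asarray(correct),
    })
    return EEGEpochs(data=data, sfreq=sfreq,
                     ch_names=["C3", "C4", "EOG"], tmin_ms=tmin_ms,
                     trials=trials)
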