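"""Parameter-recovery studies built from the published parameter sets.

Each function simulates trials from the pure DDM at published group-mean
parameters, re-fits with the quantile-multinomial engine under the matching
sharing design, and returns the recovered values next to the generating
ones.  These are the workhorses behind the acceptance checks and the
numbered analysis scripts.
"""

from __future__ import annotations

import numpy as np

from .ddm import DDMParams, choice_probability, simulate_trials
from .fitting import FitDesign, fit
from .published import EXP1_PARAMS, EXP2_PARAMS

__all__ = ["recover_coherence_conditions", "recover_arrows",
           "recover_bias_conditions", "calibration_percent_correct"]


def _split_seed(seed: int, n: int = 2) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def recover_coherence_conditions(seed: int, n_per_condition: int = 50_000,
                                 ) -> dict:
    """Joint two-condition recovery at the coherence-manipulation fits.

    Simulates both coherence conditions with an unbiased starting point and
    the shared threshold, then re-fits with drift and non-decision time free
    per condition and threshold/starting point shared — the design used for
    the published fits.
    """
    s_sim, s_fit = _split_seed(seed)
    gen = {
        "low": DDMParams.unbiased(EXP1_PARAMS["low_coherence"].drift,
                                  EXP1_PARAMS["low_coherence"].threshold,
                                  EXP1_PARAMS["low_coherence"].nondecision_t0),
        "high": DDMParams.unbiased(EXP1_PARAMS["high_coherence"].drift,
                                   EXP1_PARAMS["high_coherence"].threshold,
                                   EXP1_PARAMS["high_coherence"].nondecision_t0),
    }
    trials = simulate_trials(gen, n_per_condition, seed=s_sim)
    design = FitDesign(conditions=("low", "high"), drift="free",
                       threshold="shared", starting_point="shared",
                       nondecision_t0="free")
    res = fit(trials, design, seed=s_fit)
    return {
        "generating": gen,
        "fit": res,
        "drift_low": res.params["low"].drift,
        "drift_high": res.params["high"].drift,
        "threshold": res.params["low"].threshold,
        "t0_low": res.params["low"].nondecision_t0,
        "t0_high": res.params["high"].nondecision_t0,
        "n": n_per_condition,
    }


def recover_arrows(seed: int, n_trials: int = 50_000) -> dict:
    """Single-condition recovery at the arrows (non-integration) fit."""
    s_sim, s_fit = _split_seed(seed)
    gen = {"arrows": EXP1_PARAMS["arrows"]}
    trials = simulate_trials(gen, n_trials, seed=s_sim)
    design = FitDesign(conditions=("arrows",), drift="free", threshold="free",
                       starting_point="free", nondecision_t0="free")
    res = fit(trials, design, seed=s_fit)
    return {"generating": gen, "fit": res,
            "drift": res.params["arrows"].drift, "n": n_trials}


def recover_bias_conditions(seed: int, n_per_condition: int = 50_000) -> dict:
    """Joint recovery of the unbiased and most-biased starting points.

    Drift, threshold and non-decision time are shared across the two bias
    conditions (as in the published fits); only the starting point is free
    per condition.
    """
    s_sim, s_fit = _split_seed(seed)
    gen = {"b50": EXP2_PARAMS["0.50"], "b90": EXP2_PARAMS["0.90"]}
    trials = simulate_trials(gen, n_per_condition, seed=s_sim)
    design = FitDesign(conditions=("b50", "b90"), drift="shared",
                       threshold="shared", starting_point="free",
                       nondecision_t0="shared")
    res = fit(trials, design, seed=s_fit)
    return {"generating": gen, "fit": res,
            "z_50": res.params["b50"].starting_point,
            "z_90": res.params["b90"].starting_point,
            "n": n_per_condition}


def calibration_percent_correct() -> float:
    """Closed-form percent correct at the low-coherence fit, unbiased start.

    With z = a/2 the upper-boundary probability reduces to
    ``1 / (1 + exp(-v a / s^2))``; the coherence levels were calibrated to
    put this near 70%.
    """
    p = EXP1_PARAMS["low_coherence"]
    return 100.0 * choice_probability(DDMParams.unbiased(
        p.drift, p.threshold, p.nondecision_t0))
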