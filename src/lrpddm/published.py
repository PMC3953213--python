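"""Published group-mean pure-DDM parameter sets used as study conditions.

These are the fitted group means for a random-dot motion discrimination
study (noise coefficient fixed at s = 0.1 throughout): two coherence levels
calibrated to roughly 70% and 90% correct plus two non-integration control
conditions, and a bias manipulation in which only the starting point varies
with the probability of the preferred motion direction.
"""

from .ddm import DDMParams

#: Experiment-1-style conditions: coherence manipulation (threshold shared
#: between the two coherence levels) and the non-integration controls.
EXP1_PARAMS = {
    "low_coherence": DDMParams(drift=0.060, threshold=0.151,
                               starting_point=0.076, nondecision_t0=0.435),
    "high_coherence": DDMParams(drift=0.172, threshold=0.151,
                                starting_point=0.078, nondecision_t0=0.402),
    "arrows": DDMParams(drift=0.803, threshold=0.214,
                        starting_point=0.098, nondecision_t0=0.219),
    "signal_detection": DDMParams(drift=1.056, threshold=0.418,
                                  starting_point=0.265, nondecision_t0=0.162),
}

#: Experiment-2-style conditions: response-bias manipulation; drift,
#: threshold and non-decision time are shared and only the starting point
#: moves with the preferred-direction probability.
EXP2_PARAMS = {
    "0.50": DDMParams(drift=0.0952, threshold=0.137,
                      starting_point=0.0613, nondecision_t0=0.289),
    "0.60": DDMParams(drift=0.0952, threshold=0.137,
                      starting_point=0.0616, nondecision_t0=0.289),
    "0.75": DDMParams(drift=0.0952, threshold=0.137,
                      starting_point=0.0689, nondecision_t0=0.289),
    "0.90": DDMParams(drift=0.0952, threshold=0.137,
                      starting_point=0.0889, nondecision_t0=0.289),
}

#: preferred-direction probability per Experiment-2 condition
EXP2_PREFERRED_PROB = {"0.50": 0.50, "0.60": 0.60, "0.75": 0.75, "0.90": 0.90}
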