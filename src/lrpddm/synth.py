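"""Synthetic behavioral and EEG data with known ground truth.

Every stage of the pipeline is testable without recordings: behavior comes
from the pure DDM, and EEG epochs embed a lateralized C3/C4 template taken
from the network model's threshold-layer difference, placed per trial so the
template departs from baseline ``d1`` ms after the stimulus (perceptual
delay) and peaks ``d2`` ms before the response (motor delay).  Realistic
noise (white + 1/f per channel, plus a common-mode term that the LRP
difference cancels) and scripted artifact trials complete the fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_trials
from .lrp import EEGEpochs
from .network import NetworkParams, simulate_network_trials

__all__ = ["GroundTruth", "NoiseConfig", "gen_behavior", "gen_eeg",
           "network_template", "network_condition_templates"]


@dataclass
class NoiseConfig:
    """Additive noise for synthetic EEG, all amplitudes in µV (sd)."""

    white_uv: float = 5.0    # per-channel independent white noise
    pink_uv: float = 2.5     # per-channel independent 1/f noise
    common_uv: float = 4.0   # 1/f noise shared by all EEG channels


@dataclass
class GroundTruth:
    """What the synthetic data were built from, for recovery checks.

    params : generating DDMParams per condition
    d1_ms / d2_ms : perceptual and motor delays; the template rises from
        stimulus + d1 and peaks at response - d2, so the LRP-based
        non-decision time estimate should recover d1 + d2
    amplitude_uv : lateralized template amplitude (C3/C4 difference height)
    artifact_log : list of {"trial": index, "rule": expected rejection rule}
    """

    params: dict[str, DDMParams]
    d1_ms: float = 200.0
    d2_ms: float = 100.0
    amplitude_uv: float = 3.0
    artifact_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.d1_ms < 0 or self.d2_ms < 0:
            raise ValueError("delays must be non-negative")
        seen = [a["trial"] for a in self.artifact_log]
        if len(seen) != len(set(seen)):
            raise ValueError("at most one injected artifact per trial")


def gen_behavior(params_by_condition: dict[str, DDMParams],
                 n_per_condition: int | dict[str, int],
                 seed: int | None = None,
                 preferred_prob: dict[str, float] | None = None,
                 dt: float = 1e-4) -> pd.DataFrame:
    """Simulate a behavioral session from the pure DDM.

    Without ``preferred_prob`` every trial's correct answer is the upper
    boundary (right hand).  With it (Experiment-2 style biased blocks), the
    motion direction of each trial is drawn with the given probability of
    the preferred (upper/right) direction; the generating process keeps its
    starting-point bias toward the preferred boundary while the drift sign
    follows the true direction.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if preferred_prob is None:
        return simulate_trials(params_by_condition, n_per_condition, dt=dt,
                               seed=seed)
    rng = np.random.default_rng(seed)
    parts = []
    for cond, params in params_by_condition.items():
        n = (n_per_condition if isinstance(n_per_condition, int)
             else n_per_condition[cond])
        p_pref = preferred_prob[cond]
        n_pref = int(rng.binomial(n, p_pref))
        sub_seeds = rng.integers(0, 2**31 - 1, size=2)
        if n_pref:
            parts.append(simulate_trials(
                {cond: params}, n_pref, dt=dt, seed=int(sub_seeds[0]),
                correct_boundary="upper"))
        if n - n_pref:
            flipped = replace(params, drift=-params.drift)
            parts.append(simulate_trials(
                {cond: flipped}, n - n_pref, dt=dt, seed=int(sub_seeds[1]),
                correct_boundary="lower"))
    table = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["trial", "condition", "choice", "hand", "rt", "correct"])
    table["trial"] = np.arange(len(table))
    return table


def network_template(params: NetworkParams | None = None,
                     coherence_drive: float = 0.2,
                     clip_frac: float = 0.5,
                     taper: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Canonical LRP template from a noise-free network trial.

    Returns ``(rise, decay)``: the threshold-layer difference from its
    ballistic take-off to its peak, normalized to [0, 1], and the post-peak
    return to baseline, normalized to start at 1.  Both are resampled per
    trial by the EEG generator, so only their shapes matter.

    ``clip_frac`` drops the slow sub-threshold crawl below that fraction of
    the peak, keeping the fast saturating segment of the switch transition
    so the embedded wave has a crisp, detectable departure from baseline;
    ``taper`` applies a quarter-sine shaping that leaves the peak smooth
    (zero slope on both sides), which keeps its location invariant under
    zero-phase low-pass filtering.
    """
    p = params or NetworkParams()
    p = replace(p, noise_acc=0.0)
    tr = simulate_network_trials(p, coherence_drive, 1, seed=0)[0]
    if not tr.responded:
        raise ValueError("noise-free network trial did not respond; "
                         "increase coherence_drive")
    diff = tr.thr[0] - tr.thr[1]
    pk = int(np.argmax(diff))
    base = diff[tr.time < 0].mean()
    rise = diff[:pk + 1] - base
    start = int(np.argmax(rise > clip_frac * rise[pk]))
    rise = rise[start:]
    rise = (rise - rise[0]) / (rise[-1] - rise[0])
    rise = np.clip(rise, 0.0, 1.0)
    decay = diff[pk:] - base
    decay = np.clip(decay / decay[0], 0.0, 1.0)
    end = int(np.argmax(decay < 0.01)) or len(decay)
    decay = decay[:max(end, 2)]
    if taper:
        rise = np.sin(np.pi / 2.0 * rise)
        decay = np.sin(np.pi / 2.0 * decay)
    return rise, decay


def network_condition_templates(drives: dict[str, float],
                                params: NetworkParams | None = None,
                                n_trials: int = 400,
                                seed: int = 77,
                                window: tuple[float, float] = (-0.6, 0.25),
                                ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Response-locked LRP templates per condition from the network model.

    ``drives`` maps condition labels to coherence drives; each condition's
    template is the response-locked threshold-layer difference averaged over
    a seeded ensemble, returned on a millisecond axis for
    :func:`gen_eeg`'s ``response_locked_templates`` argument.
    """
    from .network import simulated_lrp
    p = params or NetworkParams()
    out = {}
    for cond, drive in drives.items():
        traces = simulate_network_trials(p, drive, n_trials, seed=seed)
        lrp = simulated_lrp(traces, "response", window=window)
        out[cond] = (lrp.time * 1000.0, lrp.amplitude)
    return out


def _pink_noise(rng: np.random.Generator, n: int, sd: float,
                sfreq: float) -> np.ndarray:
    """1/f-spectrum noise (power exponent 1), scaled to the given sd."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(
        len(freqs))
    x = np.fft.irfft(amp * phases, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def gen_eeg(trials: pd.DataFrame, truth: GroundTruth,
            noise: NoiseConfig | None = None,
            seed: int | None = None,
            sfreq: float = 250.0,
            extra_channels: tuple[str, ...] = ("Cz",),
            rt_max_s: float = 2.0,
            template: tuple[np.ndarray, np.ndarray] | None = None,
            decay_ms: float = 250.0,
            response_locked_templates: dict | None = None,
            ) -> tuple[EEGEpochs, GroundTruth]:
    """Build epoched EEG around the behavioral trials.

    The lateralized template is embedded antisymmetrically at C3/C4 (half
    amplitude each, signs set by response hand) so that the signed C3/C4
    difference recovers the full-amplitude template.  Trials slower than
    ``rt_max_s`` are dropped so every response fits inside its epoch.
    Artifact trials listed in ``truth.artifact_log`` get a scripted
    contamination that trips exactly the named rejection rule.

    Two embedding geometries are supported.  By default a rise/decay shape
    is warped per trial so the wave departs at stimulus + d1 and peaks at
    response - d2 (the construction behind the delay-recovery checks).
    Alternatively ``response_locked_templates`` maps each condition to a
    ``(times_ms, amplitude)`` pair on a response-relative axis (for example
    per-condition averages from the network model, see
    :func:`network_condition_templates`); each is peak-normalized and placed
    rigidly at the trial's response, which reproduces condition differences
    in waveform shape rather than in timing.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    keep = trials["rt"].to_numpy() <= rt_max_s
    trials = trials.loc[keep].reset_index(drop=True)
    n_trials = len(trials)
    if n_trials == 0:
        raise ValueError("no trials fast enough for the epoch window")

    rise, decay = template if template is not None else network_template()
    d1, d2 = truth.d1_ms, truth.d2_ms
    dt_ms = 1000.0 / sfreq
    resp_ms = trials["rt"].to_numpy() * 1000.0
    tmin = -200.0
    tmax = float(resp_ms.max()) + 250.0
    n_samp = int(round((tmax - tmin) / dt_ms)) + 1
    times = tmin + np.arange(n_samp) * dt_ms

    ch_names = ["C3", "C4", *extra_channels, "EOG"]
    eog_i = len(ch_names) - 1
    eeg_idx = [i for i in range(len(ch_names)) if i != eog_i]
    data = np.zeros((n_trials, len(ch_names), n_samp))

    # noise: independent per channel + shared common mode on EEG channels
    for i in range(n_trials):
        common = _pink_noise(rng, n_samp, noise.common_uv, sfreq)
        for c in range(len(ch_names)):
            x = (noise.white_uv * rng.standard_normal(n_samp)
                 + _pink_noise(rng, n_samp, noise.pink_uv, sfreq))
            if c in eeg_idx:
                x = x + common
            data[i, c] += x

    c3 = ch_names.index("C3")
    c4 = ch_names.index("C4")
    hands = trials["hand"].to_numpy()
    conditions = trials["condition"].to_numpy()
    if response_locked_templates is not None:
        normed = {}
        for cond, (tt, aa) in response_locked_templates.items():
            aa = np.asarray(aa, float)
            normed[cond] = (np.asarray(tt, float),
                            aa / np.nanmax(np.abs(aa)))
    for i in range(n_trials):
        if response_locked_templates is not None:
            tt, aa = normed[conditions[i]]
            shape = np.interp(times - resp_ms[i], tt,
                              np.nan_to_num(aa), left=0.0, right=0.0)
        else:
            # rise spans [stim + d1, resp - d2], then the decay
            t_on = d1
            t_peak = resp_ms[i] - d2
            if t_peak <= t_on + 2 * dt_ms:
                t_peak = t_on + 2 * dt_ms  # degenerate very fast trial
            shape = np.zeros(n_samp)
            rise_mask = (times >= t_on) & (times <= t_peak)
            if rise_mask.any():
                frac = (times[rise_mask] - t_on) / (t_peak - t_on)
                shape[rise_mask] = np.interp(
                    frac, np.linspace(0, 1, len(rise)), rise)
            dec_mask = (times > t_peak) & (times <= t_peak + decay_ms)
            if dec_mask.any():
                frac = (times[dec_mask] - t_peak) / decay_ms
                shape[dec_mask] = np.interp(
                    frac, np.linspace(0, 1, len(decay)), decay)
        half = 0.5 * truth.amplitude_uv * shape
        contra, ipsi = (c4, c3) if hands[i] == "left" else (c3, c4)
        data[i, contra] += half
        data[i, ipsi] -= half

    # scripted artifacts, each designed to trip exactly its named rule
    for entry in truth.artifact_log:
        i, rule = entry["trial"], entry["rule"]
        if i >= n_trials:
            raise ValueError(f"artifact trial {i} out of range")
        mid = n_samp // 2
        if rule == "blink":
            width = int(0.1 * sfreq)  # ~100 ms: survives the running average
            bump = 120.0 * np.exp(-0.5 * ((np.arange(n_samp) - mid)
                                          / width) ** 2)
            data[i, eog_i] += bump
        elif rule == "amplitude":
            bump = 90.0 * np.exp(-0.5 * ((np.arange(n_samp) - mid) / 1.5) ** 2)
            data[i, c3] += bump
        elif rule == "variance_high":
            data[i, c3] += 12.0 * rng.standard_normal(n_samp)
        elif rule == "variance_low":
            data[i, c3] = 0.01 * rng.standard_normal(n_samp)
        elif rule == "kurtosis":
            for off in (-40, 40):
                data[i, c3, mid + off:mid + off + 2] += 40.0
        else:
            raise ValueError(f"unknown artifact rule {rule!r}")

    meta = pd.DataFrame({
        "stim_ms": 0.0,
        "resp_ms": resp_ms,
        "hand": hands,
        "condition": trials["condition"].to_numpy(),
        "correct": trials["correct"].to_numpy(),
    })
    epochs = EEGEpochs(data=data, sfreq=sfreq, ch_names=ch_names,
                       tmin_ms=tmin, trials=meta, locking="stimulus")
    return epochs, truth
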