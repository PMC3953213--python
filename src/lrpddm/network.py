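"""Three-layer attractor network for decision commitment.

Layer 1 (*accumulation*) is a pair of leaky competing accumulators; with leak
balanced against lateral inhibition their difference approximates a
drift-diffusion process.  Layer 2 (*threshold*) is a pair of bistable switch
units — leaky integrators with strong sigmoidal self-excitation — that stay
near a low-activation state over a broad range of inputs and snap to a
high-activation state once their input crosses a critical value; this
up-transition is the network's implementation of crossing a decision
threshold.  Layer 3 (*response*) contains switch units that activate shortly
after a threshold unit turns on, trigger the overt response, and feed
inhibition back that resets the lower layers.

The signed difference between the two threshold-unit activations, averaged
over trials, is the model's stand-in for the lateralized readiness potential
(LRP); only a qualitative correspondence with microvolt-scale scalp data is
intended, so a single gain maps activation to amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NetworkParams",
    "LayerTrace",
    "SimulatedLRP",
    "switch_equilibria",
    "simulate_network_trial",
    "simulate_network_trials",
    "simulated_lrp",
    "rmsd_layer_fit",
]


@dataclass(frozen=True)
class NetworkParams:
    """Constants of the three-layer network (times in seconds).

    The default set is tuned (see analysis/03_network_predictions.py) so that
    the noise-free threshold unit is bistable at rest and the three
    qualitative LRP predictions hold: positive area between low- and
    high-drift curves in the rising phase, peak shift toward the response at
    very high drift, and baseline-to-peak height falling with response bias.
    """

    # accumulation layer
    tau_acc: float = 0.2          # accumulator time constant
    leak: float = 3.0             # leak k
    inhibition: float = 3.0       # lateral inhibition w (balanced: k == w)
    input_gain: float = 1.0       # scales stimulus input
    input_baseline: float = 0.5   # common input to both sides while stimulus on
    noise_acc: float = 0.05       # diffusion coefficient of each accumulator
    # threshold layer (bistable switch units)
    tau_thr: float = 0.08
    leak_thr: float = 1.0         # lambda
    self_excitation: float = 1.0  # alpha
    sigmoid_slope: float = 10.0   # beta_s
    sigmoid_offset: float = 0.5   # theta_s
    feedforward: float = 1.6      # accumulator -> threshold weight
    bias: tuple[float, float] = (0.0, 0.0)  # additive bias input per side
    # response layer (bistable at zero input, so it latches once triggered;
    # slow adaptation turns it off again after the response)
    tau_resp: float = 0.06
    leak_resp: float = 1.0
    self_excitation_resp: float = 1.0
    sigmoid_slope_resp: float = 10.0
    sigmoid_offset_resp: float = 0.4
    resp_input_weight: float = 0.6
    resp_detector_offset: float = 0.9   # threshold-unit level sensed by response layer
    resp_detector_slope: float = 20.0
    resp_criterion: float = 0.5         # midpoint of response unit's off/on states
    resp_adaptation_strength: float = 0.8
    tau_adapt: float = 0.3
    # reset: nearly binary response output inhibits threshold + accumulators
    reset_strength: float = 3.0
    reset_gate_slope: float = 60.0
    reset_gate_offset: float = 0.35

    def __post_init__(self):
        for name in ("tau_acc", "tau_thr", "tau_resp", "leak_thr",
                     "self_excitation", "sigmoid_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class LayerTrace:
    """Activations of all six units on a common time grid for one trial."""

    time: np.ndarray              # seconds, 0 = stimulus onset
    acc: np.ndarray               # (2, n_samples): correct side first
    thr: np.ndarray               # (2, n_samples)
    resp: np.ndarray              # (2, n_samples)
    rt: float                     # seconds; nan if no response
    choice: int                   # 0 = correct side, 1 = incorrect side, -1 none

    @property
    def responded(self) -> bool:
        return np.isfinite(self.rt)


@dataclass
class SimulatedLRP:
    """Trial-averaged threshold-layer difference (correct minus incorrect)."""

    locking: str                  # 'stimulus' or 'response'
    time: np.ndarray              # seconds relative to the locking event
    amplitude: np.ndarray
    n: int


def _sigmoid(x, slope, offset):
    return 1.0 / (1.0 + np.exp(np.clip(-slope * (x - offset), -700, 700)))


def switch_equilibria(params: NetworkParams, input_level: float,
                      u_range: tuple[float, float] | None = None,
                      n_grid: int = 4001, marginal_tol: float = 1e-6,
                      ) -> list[tuple[float, str]]:
    """Fixed points of one noise-free threshold unit at constant input.

    Solves ``-lambda u + alpha S(u) + I = 0`` by a sign scan plus root
    polishing and classifies each root by the sign of the local derivative of
    the right-hand side: negative -> stable, positive -> unstable, near zero
    -> marginal (saddle-node tangency).
    """
    lam, alpha = params.leak_thr, params.self_excitation
    slope, offset = params.sigmoid_slope, params.sigmoid_offset

    def f(u):
        return -lam * u + alpha * _sigmoid(u, slope, offset) + input_level

    def fprime(u):
        s = _sigmoid(u, slope, offset)
        return -lam + alpha * slope * s * (1.0 - s)

    if u_range is None:
        lo = min(0.0, input_level / lam) - 1.0
        hi = (alpha + max(input_level, 0.0)) / lam + 1.0
        u_range = (lo, hi)
    grid = np.linspace(u_range[0], u_range[1], n_grid)
    vals = f(grid)
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    for i in np.flatnonzero(vals == 0.0):
        roots.append(float(grid[i]))
    roots = sorted(set(np.round(roots, 10)))
    out = []
    for r in roots:
        d = fprime(r)
        kind = "marginal" if abs(d) < marginal_tol else (
            "stable" if d < 0 else "unstable")
        out.append((float(r), kind))
    return out


def threshold_tipping_input(params: NetworkParams) -> float:
    """Critical input at which the low stable state disappears (saddle-node).

    At the fold, ``-lambda u + alpha S(u) + I = 0`` and
    ``alpha beta S (1 - S) = lambda`` hold simultaneously; the branch with the
    smaller sigmoid value is the fold that annihilates the low state as input
    rises.  Returns NaN when the unit is monostable for every input.
    """
    lam, alpha = params.leak_thr, params.self_excitation
    beta, theta = params.sigmoid_slope, params.sigmoid_offset
    disc = 1.0 - 4.0 * lam / (alpha * beta)
    if disc <= 0:
        return float("nan")
    s_low = (1.0 - np.sqrt(disc)) / 2.0
    u_fold = theta + np.log(s_low / (1.0 - s_low)) / beta
    return float(lam * u_fold - alpha * s_low)


def simulate_network_trials(params: NetworkParams, coherence_drive: float,
                            n_trials: int, seed: int | None = None,
                            dt: float = 1e-3, pre_stim: float = 0.2,
                            max_time: float = 3.0, record: bool = True,
                            ):
    """Euler-Maruyama simulation of ``n_trials`` trials (vectorized).

    ``coherence_drive`` is the input advantage of the correct side: the two
    accumulators receive ``baseline +/- coherence_drive/2`` (times
    ``input_gain``) once the stimulus comes on at t = 0.  Noise enters the
    accumulation layer only.  After a response unit crosses its criterion the
    reset feedback drives the threshold and accumulation layers back down;
    integration continues to the end of the grid so post-response dynamics are
    part of every trace.

    With ``record=False`` the per-sample traces are discarded and a
    ``(rt, choice)`` array pair is returned instead of LayerTrace objects
    (useful for large behavioral ensembles).
    """
    if dt > 1e-3:
        raise ValueError("integration step must be <= 1 ms")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    p = params
    n_steps = int(round((pre_stim + max_time) / dt))
    time = np.arange(n_steps + 1) * dt - pre_stim

    # start the threshold units at their low stable state given the bias
    u0 = np.zeros(2)
    for side in (0, 1):
        eq = switch_equilibria(p, p.bias[side])
        stable = [u for u, k in eq if k == "stable"]
        u0[side] = min(stable) if stable else 0.0

    r_eq = switch_equilibria(
        NetworkParams(leak_thr=p.leak_resp,
                      self_excitation=p.self_excitation_resp,
                      sigmoid_slope=p.sigmoid_slope_resp,
                      sigmoid_offset=p.sigmoid_offset_resp), 0.0)
    r_stable = [x for x, k in r_eq if k == "stable"]
    r0 = min(r_stable) if r_stable else 0.0

    a = np.zeros((2, n_trials))
    u = np.tile(u0[:, None], (1, n_trials))
    r = np.full((2, n_trials), r0)
    w_ad = np.zeros((2, n_trials))  # response-unit adaptation
    if record:
        acc = np.zeros((2, n_trials, n_steps + 1))
        thr = np.zeros((2, n_trials, n_steps + 1))
        resp = np.zeros((2, n_trials, n_steps + 1))
        thr[:, :, 0] = u
        resp[:, :, 0] = r

    rt = np.full(n_trials, np.nan)
    choice = np.full(n_trials, -1, dtype=int)
    sq = p.noise_acc * np.sqrt(dt / p.tau_acc)
    drive = np.array([+0.5, -0.5]) * coherence_drive
    bias_col = np.asarray(p.bias)[:, None]
    I_on = p.input_gain * (p.input_baseline + drive)[:, None]
    I_off = np.zeros((2, 1))
    for step in range(n_steps):
        t = time[step]
        # stimulus stays on until this trial's response has been registered
        if t >= 0.0:
            stim_on = ~np.isfinite(rt)
        else:
            stim_on = np.zeros(n_trials, dtype=bool)
        I = np.where(stim_on[None, :], I_on, I_off)
        gate = _sigmoid(r, p.reset_gate_slope, p.reset_gate_offset).sum(axis=0)
        inhib = p.reset_strength * gate
        da = (I - p.leak * a - p.inhibition * a[::-1]
              - inhib) * (dt / p.tau_acc)
        if t >= 0.0:
            noise = (sq * rng.standard_normal((2, n_trials))
                     * stim_on[None, :])
        else:
            noise = 0.0
        a = np.maximum(a + da + noise, 0.0)

        u_in = p.feedforward * a + bias_col - inhib
        du = (-p.leak_thr * u + p.self_excitation
              * _sigmoid(u, p.sigmoid_slope, p.sigmoid_offset)
              + u_in) * (dt / p.tau_thr)
        u = u + du

        r_in = (p.resp_input_weight * _sigmoid(
            u, p.resp_detector_slope, p.resp_detector_offset)
            - p.resp_adaptation_strength * w_ad)
        dr = (-p.leak_resp * r + p.self_excitation_resp
              * _sigmoid(r, p.sigmoid_slope_resp, p.sigmoid_offset_resp)
              + r_in) * (dt / p.tau_resp)
        w_ad = w_ad + (r - w_ad) * (dt / p.tau_adapt)
        r = r + dr

        if record:
            acc[:, :, step + 1] = a
            thr[:, :, step + 1] = u
            resp[:, :, step + 1] = r

        crossed = (r > p.resp_criterion).any(axis=0) & ~np.isfinite(rt)
        if crossed.any():
            rt[crossed] = t + dt
            choice[crossed] = np.argmax(r[:, crossed], axis=0)

    if not record:
        return rt, choice
    traces = [LayerTrace(time=time, acc=acc[:, i], thr=thr[:, i],
                         resp=resp[:, i], rt=float(rt[i]),
                         choice=int(choice[i]))
              for i in range(n_trials)]
    return traces


def simulate_network_trial(params: NetworkParams, coherence_drive: float,
                           seed: int | None = None, **kwargs) -> LayerTrace:
    """Simulate a single trial; see :func:`simulate_network_trials`."""
    return simulate_network_trials(params, coherence_drive, 1, seed=seed,
                                   **kwargs)[0]


def _aligned_difference(traces, locking: str, layer: str,
                        window: tuple[float, float], correct_only: bool):
    """Stack per-trial (side0 - side1) layer differences on a common axis."""
    if not traces:
        raise ValueError("empty trial ensemble")
    dt = float(traces[0].time[1] - traces[0].time[0])
    n_out = int(round((window[1] - window[0]) / dt)) + 1
    t_out = window[0] + np.arange(n_out) * dt
    rows = []
    for tr in traces:
        if not tr.responded:
            continue
        if correct_only and tr.choice != 0:
            continue
        sig = getattr(tr, layer)
        diff = sig[0] - sig[1]
        shift = 0.0 if locking == "stimulus" else tr.rt
        idx = np.round((t_out + shift - tr.time[0]) / dt).astype(int)
        valid = (idx >= 0) & (idx < diff.size)
        row = np.full(n_out, np.nan)
        row[valid] = diff[idx[valid]]
        rows.append(row)
    if not rows:
        raise ValueError("no usable trials in ensemble")
    return t_out, np.asarray(rows)


def simulated_lrp(traces, locking: str = "response",
                  window: tuple[float, float] | None = None,
                  correct_only: bool = True) -> SimulatedLRP:
    """Average threshold-layer difference, stimulus- or response-locked.

    The difference is correct-side minus incorrect-side activation, so the
    simulated LRP is positive-going toward the decision.
    """
    if locking not in ("stimulus", "response"):
        raise ValueError("locking must be 'stimulus' or 'response'")
    if window is None:
        window = (-0.2, 1.0) if locking == "stimulus" else (-0.6, 0.2)
    t_out, rows = _aligned_difference(traces, locking, "thr", window,
                                      correct_only)
    with np.errstate(invalid="ignore"):
        amp = np.nanmean(rows, axis=0)
    return SimulatedLRP(locking=locking, time=t_out, amplitude=amp,
                        n=rows.shape[0])


def layer_average(traces, layer: str, locking: str = "response",
                  window: tuple[float, float] = (-0.6, 0.0),
                  correct_only: bool = True):
    """Trial-averaged side difference of a layer ('acc' or 'thr')."""
    t_out, rows = _aligned_difference(traces, locking, layer, window,
                                      correct_only)
    with np.errstate(invalid="ignore"):
        return t_out, np.nanmean(rows, axis=0)


def _peak_scale(trace: np.ndarray, target_height: float) -> np.ndarray:
    h = np.nanmax(np.abs(trace))
    if h == 0 or not np.isfinite(h):
        return trace
    return trace * (target_height / h)


def rmsd_layer_fit(lrp_time_s: np.ndarray, lrp_amplitude: np.ndarray,
                   params_grid, coherence_grid, seed: int,
                   n_trials: int = 200,
                   rt_window: tuple[float, float] = (0.2, 1.5),
                   ) -> dict:
    """Compare threshold- vs accumulation-layer shape against an LRP waveform.

    For every (params, coherence) grid point whose mean simulated RT lies in
    the plausibility window ``rt_window``, the response-locked trial-average
    of each layer's side difference is scaled to the LRP's peak height and the
    root-mean-square deviation from the LRP is computed over the overlapping
    time range.  Returns per-point RMSDs and the fraction of plausible points
    where the threshold layer fits better (ties count 0.5 to each layer).
    """
    lrp_time_s = np.asarray(lrp_time_s, float)
    lrp_amplitude = np.asarray(lrp_amplitude, float)
    height = float(np.nanmax(np.abs(lrp_amplitude)))
    rng = np.random.default_rng(seed)
    records = []
    wins = 0.0
    n_plausible = 0
    for params in params_grid:
        for coh in coherence_grid:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            traces = simulate_network_trials(params, coh, n_trials,
                                             seed=sub_seed)
            rts = np.array([tr.rt for tr in traces if tr.responded])
            if rts.size == 0:
                continue
            mean_rt = float(rts.mean())
            plausible = rt_window[0] <= mean_rt <= rt_window[1]
            rec = {"coherence_drive": coh, "mean_rt": mean_rt,
                   "plausible": plausible, "rmsd_threshold_layer": np.nan,
                   "rmsd_accumulation_layer": np.nan}
            if plausible:
                window = (float(lrp_time_s[0]), float(lrp_time_s[-1]))
                for layer, key in (("thr", "rmsd_threshold_layer"),
                                   ("acc", "rmsd_accumulation_layer")):
                    t_mod, avg = layer_average(traces, layer,
                                               locking="response",
                                               window=window)
                    model = np.interp(lrp_time_s, t_mod, avg)
                    model = _peak_scale(model, height)
                    rec[key] = float(np.sqrt(np.nanmean(
                        (model - lrp_amplitude) ** 2)))
                n_plausible += 1
                if rec["rmsd_threshold_layer"] < rec["rmsd_accumulation_layer"]:
                    wins += 1.0
                elif rec["rmsd_threshold_layer"] == rec["rmsd_accumulation_layer"]:
                    wins += 0.5
            records.append(rec)
    if n_plausible == 0:
        raise ValueError("no grid point produced responses inside the "
                         "plausibility window")
    return {"grid": records,
            "n_plausible": n_plausible,
            "threshold_win_fraction": wins / n_plausible}
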