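"""Lateralized readiness potential (LRP) pipeline.

The LRP isolates hand-specific motor preparation from EEG recorded over the
motor cortices: the potential at C3 (left hemisphere) is subtracted from C4
for left-hand responses and C4 from C3 for right-hand responses, and the
signed differences are averaged over trials.  This module provides the
container for epoched EEG, low-pass filtering, per-trial artifact rejection,
LRP computation with stimulus- or response-locked re-epoching and baseline
correction, and the scalar measures taken from the waveform: onset latency by
one-degree-of-freedom piecewise regression, peak latency and baseline-to-peak
height, area between two condition waveforms, and the LRP-based estimate of
non-decision time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.stats import kurtosis

__all__ = [
    "EEGEpochs",
    "LRPWaveform",
    "LRPMeasures",
    "RejectionReport",
    "lowpass",
    "reject_artifacts",
    "compute_lrp",
    "grand_average",
    "onset_1df",
    "peak_measures",
    "area_between",
    "measure_lrp",
    "neural_t0",
]

# default epoch windows (ms relative to the locking event)
STIM_WINDOW = (-200.0, 1500.0)
RESP_WINDOW = (-600.0, 200.0)
STIM_BASELINE = (-200.0, 0.0)    # immediately preceding stimulus onset
RESP_BASELINE = (-600.0, -400.0)  # 400-600 ms before the response


def _ms_to_sample(t_ms, sfreq: float):
    """Map times in ms to sample counts, rounding half away from zero."""
    x = np.asarray(t_ms, dtype=float) * sfreq / 1000.0
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class EEGEpochs:
    """Epoched multichannel EEG with per-trial events and metadata.

    data : array (n_trials, n_channels, n_samples), microvolts
    sfreq : sampling rate, Hz
    ch_names : channel labels; must include C3, C4 and an eye channel
    tmin_ms : time of the first sample relative to stimulus onset (ms)
    trials : DataFrame with per-trial columns ``stim_ms`` (stimulus onset
        within the epoch, usually 0), ``resp_ms`` (response latency),
        ``hand`` ('left'/'right'), ``condition``, ``correct``
    locking : tag naming the event at epoch time zero
    eog_channel : label of the eye channel used for blink detection
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    tmin_ms: float
    trials: pd.DataFrame
    locking: str = "stimulus"
    eog_channel: str = "EOG"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("channel label count does not match data")
        for ch in ("C3", "C4", self.eog_channel):
            if ch not in self.ch_names:
                raise ValueError(f"required channel {ch!r} missing")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata length does not match data")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contains NaNs")
        need = {"stim_ms", "resp_ms", "hand", "condition", "correct"}
        missing = need - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial metadata missing columns: {sorted(missing)}")
        t = self.times_ms
        for col in ("stim_ms", "resp_ms"):
            lat = self.trials[col].to_numpy(dtype=float)
            if ((lat < t[0]) | (lat > t[-1])).any():
                raise ValueError(f"{col} outside the epoch for some trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.ch_names.index(name), :]

    def select(self, mask) -> "EEGEpochs":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask],
                       trials=self.trials.iloc[mask].reset_index(drop=True))

    # ---- persistence: HDF5 voltage block + JSON sidecar for metadata ----

    def save(self, h5_path, sidecar_path=None) -> None:
        h5_path = str(h5_path)
        sidecar_path = sidecar_path or h5_path.rsplit(".", 1)[0] + ".json"
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("data", data=self.data)
        meta = {
            "sfreq": self.sfreq,
            "ch_names": list(self.ch_names),
            "tmin_ms": self.tmin_ms,
            "locking": self.locking,
            "eog_channel": self.eog_channel,
            "trials": self.trials.to_dict(orient="list"),
        }
        with open(sidecar_path, "w") as f:
            json.dump(meta, f)

    @classmethod
    def load(cls, h5_path, sidecar_path=None) -> "EEGEpochs":
        h5_path = str(h5_path)
        sidecar_path = sidecar_path or h5_path.rsplit(".", 1)[0] + ".json"
        with h5py.File(h5_path, "r") as f:
            data = f["data"][()]
        with open(sidecar_path) as f:
            meta = json.load(f)
        return cls(data=data, sfreq=meta["sfreq"], ch_names=meta["ch_names"],
                   tmin_ms=meta["tmin_ms"],
                   trials=pd.DataFrame(meta["trials"]),
                   locking=meta.get("locking", "stimulus"),
                   eog_channel=meta.get("eog_channel", "EOG"))


@dataclass
class LRPWaveform:
    """Averaged LRP difference wave for one condition and locking."""

    locking: str
    time_ms: np.ndarray
    amplitude_uv: np.ndarray
    n: int
    condition: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("waveform must average at least one trial")
        if not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time axis must be strictly increasing")


@dataclass
class LRPMeasures:
    """Scalar LRP measurements feeding the cross-subject analyses."""

    onset_ms: float = np.nan
    peak_latency_ms: float = np.nan
    peak_height_uv: float = np.nan
    area_uv_ms: dict = field(default_factory=dict)
    neural_t0_ms: float = np.nan


@dataclass
class RejectionReport:
    """Artifact rejection outcome: per-rule counts and trial indices."""

    n_total: int
    n_rejected: int
    by_rule: dict          # rule -> sorted list of first-match trial indices
    all_matches: dict      # rule -> every trial the rule flagged
    rejected: np.ndarray   # sorted indices of all rejected trials


def lowpass(epochs: EEGEpochs, cutoff_hz: float = 4.0, order: int = 4,
            ) -> EEGEpochs:
    """Zero-phase Butterworth low-pass; DC is preserved.

    The default 4 Hz cutoff matches common LRP practice; results are robust
    to much higher cutoffs, so the parameter is exposed.
    """
    nyq = epochs.sfreq / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = butter(order, cutoff_hz, btype="low", fs=epochs.sfreq, output="sos")
    return replace(epochs, data=sosfiltfilt(sos, epochs.data, axis=-1))


# artifact rules in attribution order: a large transient necessarily raises
# kurtosis as well, so each rejected trial is attributed to the first rule
# that flags it, and all matches are reported separately
ARTIFACT_RULE_ORDER = ("blink", "amplitude", "variance_high", "variance_low",
                       "kurtosis")


def reject_artifacts(epochs: EEGEpochs,
                     blink_uv: float = 100.0,
                     blink_window_ms: float = 100.0,
                     amplitude_uv: float = 70.0,
                     variance_high: float = 80.0,
                     variance_low: float = 0.1,
                     kurtosis_max: float = 5.0,
                     ) -> tuple[EEGEpochs, RejectionReport]:
    """Remove artifact trials and report which rule flagged each.

    Rules (defaults follow standard ERP practice): a running
    ``blink_window_ms`` average of the eye channel exceeding ``blink_uv``;
    any EEG channel's absolute amplitude above ``amplitude_uv``; per-channel
    variance above ``variance_high`` or below ``variance_low`` (in µV²); or
    per-channel (Pearson) kurtosis above ``kurtosis_max``.  Amplitude,
    variance and kurtosis rules apply to the non-EOG channels.
    """
    eeg_idx = [i for i, ch in enumerate(epochs.ch_names)
               if ch != epochs.eog_channel]
    eeg = epochs.data[:, eeg_idx, :]
    eog = epochs.channel(epochs.eog_channel)

    win = max(int(round(blink_window_ms * epochs.sfreq / 1000.0)), 1)
    kernel = np.ones(win) / win
    running = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="valid"), -1, eog)
    matches = {
        "blink": np.abs(running).max(axis=-1) > blink_uv,
        "amplitude": np.abs(eeg).max(axis=(1, 2)) > amplitude_uv,
        "variance_high": eeg.var(axis=-1).max(axis=-1) > variance_high,
        "variance_low": eeg.var(axis=-1).min(axis=-1) < variance_low,
        "kurtosis": kurtosis(eeg, axis=-1, fisher=False).max(axis=-1)
        > kurtosis_max,
    }
    attributed = {rule: [] for rule in ARTIFACT_RULE_ORDER}
    rejected = np.zeros(epochs.n_trials, dtype=bool)
    for rule in ARTIFACT_RULE_ORDER:
        new = matches[rule] & ~rejected
        attributed[rule] = np.flatnonzero(new).tolist()
        rejected |= matches[rule]
    if rejected.all():
        raise ValueError("artifact rejection removed every trial")
    report = RejectionReport(
        n_total=epochs.n_trials,
        n_rejected=int(rejected.sum()),
        by_rule=attributed,
        all_matches={r: np.flatnonzero(m).tolist()
                     for r, m in matches.items()},
        rejected=np.flatnonzero(rejected),
    )
    return epochs.select(~rejected), report


def _reepoch(sig: np.ndarray, times_ms: np.ndarray, sfreq: float,
             event_ms: np.ndarray, window: tuple[float, float]):
    """Cut per-trial windows around per-trial events; NaN outside the epoch."""
    dt = 1000.0 / sfreq
    n_out = int(_ms_to_sample(window[1] - window[0], sfreq)) + 1
    t_out = window[0] + np.arange(n_out) * dt
    out = np.full((sig.shape[0], n_out), np.nan)
    start = _ms_to_sample(event_ms + window[0] - times_ms[0], sfreq).astype(int)
    for i, s0 in enumerate(start):
        idx = s0 + np.arange(n_out)
        ok = (idx >= 0) & (idx < sig.shape[1])
        out[i, ok] = sig[i, idx[ok]]
    return t_out, out


def compute_lrp(epochs: EEGEpochs, locking: str = "response",
                condition: str | None = None,
                window: tuple[float, float] | None = None,
                baseline: tuple[float, float] | None = None,
                positive_up: bool = True) -> LRPWaveform:
    """Average signed C3/C4 difference over correct trials.

    Per trial the difference is C4 - C3 for left-hand responses and C3 - C4
    for right-hand responses; trials are re-epoched around the stimulus or
    the response, baseline-corrected per trial (stimulus-locked: mean of the
    200 ms before stimulus onset; response-locked: mean of 400-600 ms before
    the response) and averaged.  ``positive_up`` orients the wave so the
    pre-response deflection is positive-going.
    """
    if locking not in ("stimulus", "response"):
        raise ValueError("locking must be 'stimulus' or 'response'")
    # copy: to_numpy can alias the underlying column and &= would mutate it
    sel = epochs.trials["correct"].to_numpy(dtype=bool, copy=True)
    if condition is not None:
        sel &= (epochs.trials["condition"] == condition).to_numpy()
    if not sel.any():
        raise ValueError("no correct trials to average")
    sub = epochs.select(sel)
    hands = sub.trials["hand"].to_numpy()
    if not np.isin(hands, ("left", "right")).all():
        raise ValueError("hand labels must be 'left' or 'right'")
    sign = np.where(hands == "left", 1.0, -1.0)
    diff = sign[:, None] * (sub.channel("C4") - sub.channel("C3"))

    window = window or (STIM_WINDOW if locking == "stimulus" else RESP_WINDOW)
    baseline = baseline or (STIM_BASELINE if locking == "stimulus"
                            else RESP_BASELINE)
    event = (sub.trials["stim_ms"] if locking == "stimulus"
             else sub.trials["resp_ms"]).to_numpy(dtype=float)
    t_out, cut = _reepoch(diff, sub.times_ms, sub.sfreq, event, window)
    bl_mask = (t_out >= baseline[0]) & (t_out <= baseline[1])
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cut = cut - np.nanmean(cut[:, bl_mask], axis=1, keepdims=True)
        amp = np.nanmean(cut, axis=0)
    # trim the edges of the requested window that no trial's epoch covers
    valid = ~np.isnan(amp)
    if not valid.any():
        raise ValueError("requested window lies outside every epoch")
    lo, hi = np.flatnonzero(valid)[[0, -1]]
    t_out, amp = t_out[lo:hi + 1], amp[lo:hi + 1]
    if np.isnan(amp).any():
        raise ValueError("window has interior gaps across trials")
    if not positive_up:
        amp = -amp
    return LRPWaveform(locking=locking, time_ms=t_out, amplitude_uv=amp,
                       n=int(sel.sum()), condition=condition or "")


def grand_average(waveforms: list[LRPWaveform]) -> LRPWaveform:
    """Unweighted mean across subjects (waveforms share a time axis)."""
    if not waveforms:
        raise ValueError("nothing to average")
    t = waveforms[0].time_ms
    for w in waveforms[1:]:
        if w.locking != waveforms[0].locking or not np.array_equal(w.time_ms, t):
            raise ValueError("waveforms must share locking and time axis")
    amp = np.mean([w.amplitude_uv for w in waveforms], axis=0)
    return LRPWaveform(locking=waveforms[0].locking, time_ms=t,
                       amplitude_uv=amp, n=len(waveforms),
                       condition=waveforms[0].condition)


def onset_1df(lrp: LRPWaveform, search_window_ms: tuple[float, float],
              min_segment: int = 3, rise_fraction: float = 0.6) -> float:
    """Onset latency by 1-degree-of-freedom piecewise regression.

    Fits a slope-zero line (at the initial-segment mean) and a least-squares
    line to the rise, for every candidate breakpoint inside the search
    window; the onset is where the two lines of the SSE-minimizing split
    intersect.  Ties take the earliest breakpoint.  Raises if no rising
    segment exists.
    """
    t = lrp.time_ms
    y = lrp.amplitude_uv
    mask = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    ti, yi = t[mask], y[mask]
    n = len(ti)
    if n < 2 * min_segment + 1:
        raise ValueError("search window too short")
    # fit the rising line only up to rise_fraction of the window maximum:
    # beyond that the wave saturates toward its peak and a line fitted
    # through the shoulder would misplace the intersection
    y_max = float(yi.max())
    above = np.flatnonzero(yi >= rise_fraction * y_max)
    rise_end = int(above[0]) + 1 if above.size else n
    best = None
    for b in range(min_segment, n - min_segment):
        flat = yi[:b]
        level = flat.mean()
        sse = float(((flat - level) ** 2).sum())
        end = max(rise_end, b + min_segment)
        tr, yr = ti[b:end], yi[b:end]
        A = np.column_stack([tr - tr[0], np.ones_like(tr)])
        coef, res, *_ = np.linalg.lstsq(A, yr, rcond=None)
        slope, intercept = coef
        sse += float(res[0]) if res.size else float(
            ((A @ coef - yr) ** 2).sum())
        if slope <= 0:
            continue
        if best is None or sse < best[0] - 1e-12:
            cross = tr[0] + (level - intercept) / slope
            best = (sse, b, float(cross))
    if best is None:
        raise ValueError("no rise detected in the search window")
    # the flat/rising intersection, kept inside the searched window
    return float(np.clip(best[2], ti[0], ti[-1]))


def _local_maxima(y: np.ndarray, min_prominence: float = 0.0) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima (earliest of a
    plateau), optionally discarding bumps with small prominence.

    ``min_prominence`` is a fraction of the waveform's peak-to-trough range;
    it suppresses noise wiggles that the original visual-inspection step
    would have ignored.
    """
    idx = [i for i in range(1, len(y) - 1)
           if y[i] > y[i - 1] and y[i] >= y[i + 1]]
    if not idx or min_prominence <= 0:
        return np.asarray(idx, dtype=int)
    from scipy.signal import peak_prominences
    prom = peak_prominences(y, idx)[0]
    thresh = min_prominence * float(np.ptp(y))
    return np.asarray([i for i, p in zip(idx, prom) if p >= thresh],
                      dtype=int)


def peak_measures(lrp: LRPWaveform, rt_ref_ms: float | None = None,
                  onset_ms: float | None = None,
                  search_window_ms: tuple[float, float] | None = None,
                  min_prominence: float = 0.15) -> tuple[float, float]:
    """Peak latency and height under the locking-appropriate definition.

    Stimulus-locked: the first local maximum before ``rt_ref_ms`` (typically
    the median RT); height is the distance from the waveform at its onset
    (``onset_ms``, estimated here if not given) to that peak.
    Response-locked: the last local maximum before the response (t = 0);
    height is the distance from the preceding trough to that peak.
    """
    t, y = lrp.time_ms, lrp.amplitude_uv
    if lrp.locking == "stimulus":
        if rt_ref_ms is None:
            raise ValueError("stimulus-locked peak needs rt_ref_ms")
        lo = t[0] if search_window_ms is None else search_window_ms[0]
        mask = (t >= lo) & (t <= rt_ref_ms)
        cand = (_local_maxima(y, min_prominence) if mask.any()
                else np.array([], int))
        cand = cand[mask[cand]] if cand.size else cand
        if cand.size == 0:
            raise ValueError("no local maximum before the RT bound")
        pk = cand[0]
        if onset_ms is None:
            onset_ms = onset_1df(lrp, (t[0], t[pk]))
        y_onset = float(np.interp(onset_ms, t, y))
        return float(t[pk]), float(y[pk] - y_onset)
    # response-locked
    mask = t < 0
    cand = _local_maxima(y, min_prominence)
    cand = cand[mask[cand]] if cand.size else cand
    if cand.size == 0:
        raise ValueError("no local maximum before the response")
    pk = cand[-1]
    before = y[:pk]
    troughs = _local_maxima(-before)
    trough_val = before[troughs[-1]] if troughs.size else float(np.min(before))
    return float(t[pk]), float(y[pk] - trough_val)


def area_between(lrp_low: LRPWaveform, lrp_high: LRPWaveform,
                 window_ms: tuple[float, float]) -> float:
    """Trapezoidal integral of (low - high) over the window, in µV·ms.

    Positive when the low-drift (slower) waveform lies above the high-drift
    waveform inside the window, matching the sign convention under which
    larger drift differences produce larger positive areas.
    """
    if not np.array_equal(lrp_low.time_ms, lrp_high.time_ms):
        raise ValueError("waveforms must share a time axis")
    t = lrp_low.time_ms
    if window_ms[0] < t[0] or window_ms[1] > t[-1]:
        raise ValueError("window outside the waveforms' overlap")
    d = lrp_low.amplitude_uv - lrp_high.amplitude_uv
    inner = (t > window_ms[0]) & (t < window_ms[1])
    # interpolate the exact window edges so the integral spans the full span
    grid = np.concatenate(([window_ms[0]], t[inner], [window_ms[1]]))
    vals = np.concatenate(([np.interp(window_ms[0], t, d)], d[inner],
                           [np.interp(window_ms[1], t, d)]))
    return float(np.trapezoid(vals, grid))


def measure_lrp(stim_lrp: LRPWaveform, resp_lrp: LRPWaveform,
                rt_ref_ms: float,
                area_windows: dict | None = None,
                other: dict[str, LRPWaveform] | None = None,
                onset_start_ms: float = -100.0) -> LRPMeasures:
    """All scalar measures from a stimulus-/response-locked waveform pair.

    The onset search runs from the start of the stimulus-locked waveform to
    its largest value before ``rt_ref_ms`` (median RT); peak latency/height
    follow the response-locked last-peak-before-response rule; the neural
    non-decision time adds the onset to the response-locked peak-to-response
    distance.  ``area_windows`` maps labels to (lo, hi) ms windows measured
    against the matching waveform in ``other`` (same locking as resp_lrp).
    """
    t, y = stim_lrp.time_ms, stim_lrp.amplitude_uv
    pre = (t <= rt_ref_ms)
    stim_peak_ms = float(t[pre][np.argmax(y[pre])])
    onset = onset_1df(stim_lrp, (max(onset_start_ms, float(t[0])),
                                 stim_peak_ms))
    peak_lat, peak_h = peak_measures(resp_lrp)
    areas = {}
    for label, win in (area_windows or {}).items():
        areas[label] = area_between(resp_lrp, other[label], win)
    return LRPMeasures(onset_ms=onset, peak_latency_ms=peak_lat,
                       peak_height_uv=peak_h, area_uv_ms=areas,
                       neural_t0_ms=onset + abs(peak_lat))


def neural_t0(stim_lrp: LRPWaveform, resp_lrp: LRPWaveform,
              onset_search_ms: tuple[float, float]) -> float:
    """LRP-based non-decision time estimate, in ms.

    The time the stimulus-locked LRP departs from baseline (a perceptual
    latency) plus the distance from the response-locked peak to the response
    (a motor latency).
    """
    onset = onset_1df(stim_lrp, onset_search_ms)
    peak_lat, _ = peak_measures(resp_lrp)
    return float(onset + abs(peak_lat))
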