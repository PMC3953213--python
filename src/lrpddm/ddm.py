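"""Pure drift-diffusion model: closed forms, first-passage densities, simulation.

The pure (Wiener) DDM describes two-choice decisions as a Brownian motion with
drift ``v`` and infinitesimal standard deviation ``s`` that starts at ``z`` and
terminates when it reaches either of two absorbing boundaries placed at ``0``
(lower) and ``a`` (upper).  Observed response time is the first-passage time
plus a non-decision time ``t0`` covering perceptual and motor latencies.
Following the convention common in the RT-modelling literature, the noise
coefficient is fixed at ``s = 0.1`` so that drift, boundary separation and
starting point are identified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DDMParams",
    "choice_probability",
    "mean_decision_time",
    "first_passage_density",
    "first_passage_cdf",
    "simulate_trials",
    "read_trial_table",
    "write_trial_table",
]

#: Conventional fixed scaling of the diffusion coefficient.
DEFAULT_NOISE = 0.1

# Euler first-passage times are biased high because the path can cross and
# return between grid points; shrinking both boundaries inward by
# 0.5826*s*sqrt(dt) (the Broadie-Glasserman-Kou continuity correction) removes
# the O(sqrt(dt)) component of that bias.
_BGK_BETA = 0.5826


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the pure DDM for a single condition.

    drift : evidence units / s
    threshold : boundary separation ``a`` (evidence units), upper boundary
    starting_point : ``z`` in (0, a)
    nondecision_t0 : seconds added to every first-passage time
    noise_s : diffusion coefficient (evidence units / sqrt(s)); fixed at 0.1
        by convention
    """

    drift: float
    threshold: float
    starting_point: float
    nondecision_t0: float
    noise_s: float = DEFAULT_NOISE

    def __post_init__(self) -> None:
        if not np.isfinite([self.drift, self.threshold, self.starting_point,
                            self.nondecision_t0, self.noise_s]).all():
            raise ValueError("DDM parameters must be finite")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not (0 < self.starting_point < self.threshold):
            raise ValueError(
                f"starting point must lie strictly between the boundaries: "
                f"z={self.starting_point}, a={self.threshold}"
            )
        if self.nondecision_t0 < 0:
            raise ValueError("non-decision time must be >= 0")
        if self.noise_s <= 0:
            raise ValueError("noise coefficient must be > 0")

    @classmethod
    def unbiased(cls, drift: float, threshold: float, nondecision_t0: float,
                 noise_s: float = DEFAULT_NOISE) -> "DDMParams":
        """Parameters with the starting point midway between the boundaries."""
        return cls(drift, threshold, threshold / 2.0, nondecision_t0, noise_s)

    def flipped(self) -> "DDMParams":
        """Mirror the process: v -> -v, z -> a - z (swaps the boundaries)."""
        return replace(self, drift=-self.drift,
                       starting_point=self.threshold - self.starting_point)


def _normalized(params: DDMParams) -> tuple[float, float, float]:
    """Return (vt, w, tscale): drift and start of the unit-boundary process.

    Space is scaled by ``a`` and time by ``a^2 / s^2`` so the process has unit
    boundary separation and unit diffusion; ``vt = v*a/s^2`` is the scaled
    drift and ``w = z/a`` the relative starting point.
    """
    vt = params.drift * params.threshold / params.noise_s**2
    w = params.starting_point / params.threshold
    tscale = params.noise_s**2 / params.threshold**2
    return vt, w, tscale


def choice_probability(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Uses the classical gambler's-ruin formula
    ``P(upper) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2))``,
    which reduces to ``z / a`` as ``v -> 0``.
    """
    vt, w, _ = _normalized(params)
    if abs(vt) < 1e-8:
        # first-order series in vt, exact limit at vt = 0
        return w + vt * w * (1.0 - w)
    if vt > 0:
        return float(np.expm1(-2.0 * vt * w) / np.expm1(-2.0 * vt))
    # mirror for negative drift to avoid overflowing exponentials
    mirrored = float(np.expm1(2.0 * vt * (1.0 - w)) / np.expm1(2.0 * vt))
    return 1.0 - mirrored


def mean_decision_time(params: DDMParams) -> float:
    """Expected first-passage (decision) time in seconds, either boundary.

    General absorbing-boundary result
    ``E[T] = (a/v) P(upper) - z/v`` for ``v != 0``; as ``v -> 0`` this tends to
    ``z (a - z) / s^2``.  For an unbiased starting point it reduces to
    ``(a / 2v) tanh(v a / 2 s^2)``.
    """
    v, a, z, s = (params.drift, params.threshold, params.starting_point,
                  params.noise_s)
    vt = v * a / s**2
    if abs(vt) < 1e-6:
        return z * (a - z) / s**2  # v -> 0 limit; O(vt) error is negligible here
    return (a * choice_probability(params) - z) / v


def _fpt_density_lower_unit(tau: np.ndarray, vt: float, w: float,
                            tol: float = 1e-10, max_terms: int = 100_000,
                            ) -> np.ndarray:
    """Density of absorption at the *lower* boundary for the unit process.

    Evaluates the Feller series in whichever representation converges faster
    (small-time image expansion vs. large-time eigenfunction expansion),
    truncating once additional terms fall below ``tol``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]
    drift_fac = np.exp(np.clip(-vt * w - vt**2 * t / 2.0, -700, 700))

    # term-count heuristics (Navarro & Fuss 2009 style)
    k_small = np.where(
        2.0 * np.sqrt(2.0 * np.pi * t) * tol < 1.0,
        2.0 + np.sqrt(-2.0 * t * np.log(2.0 * tol * np.sqrt(2.0 * np.pi * t))),
        2.0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        k_large = np.where(
            np.pi * t * tol < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * tol), 0.0)
                    / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
    use_small = k_small < k_large

    dens = np.empty_like(t)
    if use_small.any():
        ts = t[use_small]
        K = int(min(max_terms, np.ceil(k_small[use_small].max() / 2.0) + 1))
        j = np.arange(-K, K + 1)[:, None]
        terms = (w + 2.0 * j) * np.exp(-((w + 2.0 * j) ** 2) / (2.0 * ts))
        dens[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)
    if (~use_small).any():
        tl = t[~use_small]
        K = int(min(max_terms, np.ceil(k_large[~use_small].max()) + 1))
        k = np.arange(1, K + 1)[:, None]
        terms = k * np.sin(k * np.pi * w) * np.exp(-(k**2) * np.pi**2 * tl / 2.0)
        dens[~use_small] = np.pi * terms.sum(axis=0)
    out[pos] = np.maximum(dens * drift_fac, 0.0)
    return out


def first_passage_density(t, params: DDMParams, boundary: str = "upper",
                          tol: float = 1e-10):
    """Defective first-passage-time density at decision time ``t`` (seconds).

    ``t`` is measured from accumulation onset (non-decision time excluded).
    The density for each boundary integrates to that boundary's choice
    probability; the two boundary densities together integrate to one.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    p = params if boundary == "lower" else params.flipped()
    vt, w, tscale = _normalized(p)
    tau = np.asarray(t, dtype=float) * tscale
    dens = _fpt_density_lower_unit(tau, vt, w, tol=tol) * tscale
    if not np.isfinite(dens).all():
        raise FloatingPointError(
            f"first-passage density series failed to converge at t={t!r}, "
            f"params={params!r}"
        )
    return dens if np.ndim(t) else float(dens)


def _fpt_cdf_lower_unit(tau: np.ndarray, vt: float, w: float,
                        tol: float = 1e-12, max_terms: int = 100_000,
                        ) -> np.ndarray:
    """Defective CDF of lower-boundary absorption for the unit process.

    Term-by-term integral of the large-time eigenfunction expansion:
    ``F(tau) = P_lower - pi exp(-vt w) sum_k k sin(k pi w) exp(-L_k tau)/L_k``
    with ``L_k = (vt^2 + k^2 pi^2) / 2``.
    """
    tau = np.asarray(tau, dtype=float)
    p_lower = 1.0 - choice_probability(
        DDMParams(vt, 1.0, w, 0.0, 1.0))
    out = np.full_like(tau, p_lower, dtype=float)
    pos = tau > 0
    out[~pos] = 0.0
    if not pos.any():
        return out
    t = tau[pos]
    tmin = float(t.min())
    # choose K so the K-th term is below tol at the smallest tau requested
    K = 10
    while K < max_terms:
        lam = (vt**2 + K**2 * np.pi**2) / 2.0
        if np.pi * K / lam * np.exp(-lam * tmin) < tol:
            break
        K *= 2
    k = np.arange(1, K + 1)[:, None]
    lam = (vt**2 + k**2 * np.pi**2) / 2.0
    pref = np.exp(np.clip(-vt * w, -700, 700))
    series = (k * np.sin(k * np.pi * w) / lam * np.exp(-lam * t)).sum(axis=0)
    vals = p_lower - np.pi * pref * series
    out[pos] = np.clip(vals, 0.0, 1.0)
    return out


def first_passage_cdf(t, params: DDMParams, boundary: str = "upper"):
    """Defective CDF ``P(T <= t, absorbed at boundary)`` at decision time t."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    p = params if boundary == "lower" else params.flipped()
    vt, w, tscale = _normalized(p)
    tau = np.asarray(t, dtype=float) * tscale
    cdf = _fpt_cdf_lower_unit(tau, vt, w)
    return cdf if np.ndim(t) else float(cdf)


def simulate_trials(params_by_condition: dict[str, DDMParams],
                    n_per_condition: int | dict[str, int],
                    dt: float = 1e-4,
                    seed: int | None = None,
                    max_time: float = 30.0,
                    correct_boundary: str = "upper",
                    overshoot_correction: bool = True) -> pd.DataFrame:
    """Simulate DDM trials by Euler-Maruyama and return a trial table.

    Each trial integrates ``dX = v dt + s sqrt(dt) N(0,1)`` from ``z`` until a
    boundary is reached; RT is the crossing time plus ``t0``.  Choices map to
    response hands: upper -> right, lower -> left.  ``correct_boundary`` names
    the boundary that counts as a correct response for every condition.

    Trials that fail to terminate within ``max_time`` seconds of decision time
    are dropped with a warning (they are counted in the returned table's
    attrs under ``"n_nonterminated"``).
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for cond, params in params_by_condition.items():
        n = (n_per_condition if isinstance(n_per_condition, int)
             else n_per_condition[cond])
        if n == 0:
            continue
        v, a, z, s = (params.drift, params.threshold, params.starting_point,
                      params.noise_s)
        shrink = _BGK_BETA * s * np.sqrt(dt) if overshoot_correction else 0.0
        lo, hi = shrink, a - shrink
        x = np.full(n, z)
        t_cross = np.full(n, np.nan)
        upper = np.zeros(n, dtype=bool)
        active = np.arange(n)
        sqdt = s * np.sqrt(dt)
        n_steps = int(np.ceil(max_time / dt))
        for step in range(1, n_steps + 1):
            x[active] += v * dt + sqdt * rng.standard_normal(active.size)
            xa = x[active]
            crossed = (xa >= hi) | (xa <= lo)
            if crossed.any():
                hit = active[crossed]
                t_cross[hit] = step * dt
                upper[hit] = xa[crossed] >= hi
                active = active[~crossed]
                if active.size == 0:
                    break
        n_dropped += active.size
        done = np.isfinite(t_cross)
        choice = np.where(upper[done], "upper", "lower")
        rows.append(pd.DataFrame({
            "condition": cond,
            "choice": choice,
            "hand": np.where(choice == "upper", "right", "left"),
            "rt": t_cross[done] + params.nondecision_t0,
            "correct": choice == correct_boundary,
        }))
    if n_dropped:
        import warnings
        warnings.warn(f"{n_dropped} trial(s) did not terminate within "
                      f"{max_time} s and were excluded")
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["condition", "choice", "hand", "rt",
                                      "correct"])
    table.insert(0, "trial", np.arange(len(table)))
    table.attrs["n_nonterminated"] = n_dropped
    return table


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (header: trial,condition,choice,hand,rt,correct)."""
    table.to_csv(path, index=False,
                 columns=["trial", "condition", "choice", "hand", "rt",
                          "correct"])


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the required columns."""
    table = pd.read_csv(path)
    required = {"trial", "condition", "choice", "hand", "rt", "correct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if (table["rt"] <= 0).any():
        raise ValueError("trial table contains non-positive RTs")
    return table
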