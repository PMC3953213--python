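"""Quantile-based maximum-likelihood fitting of the pure DDM.

The observed RT distribution of each condition x choice cell is summarized by
its RT quantiles (default 0.1, 0.3, 0.5, 0.7, 0.9); the counts falling between
successive quantiles form a multinomial whose cell probabilities are predicted
from the Wiener first-passage distribution.  Maximizing this multinomial
likelihood (a QMPE-style objective) recovers drift, boundary separation,
starting point and non-decision time.  Parameters may be shared across
conditions or left free per condition, and competing sharing designs are
compared by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ddm import DDMParams, DEFAULT_NOISE, choice_probability, first_passage_cdf

__all__ = ["FitDesign", "FitResult", "fit", "ez_init", "bic"]

PARAM_FIELDS = ("drift", "threshold", "starting_point", "nondecision_t0")
DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

_PENALTY = 1e10
_MIN_CELL_FOR_QUANTILES = 10


@dataclass(frozen=True)
class FitDesign:
    """Maps each DDM parameter to 'shared' (one value) or 'free' (per condition)."""

    conditions: tuple[str, ...]
    drift: str = "free"
    threshold: str = "shared"
    starting_point: str = "free"
    nondecision_t0: str = "free"

    def __post_init__(self):
        if len(self.conditions) == 0:
            raise ValueError("at least one condition is required")
        for f in PARAM_FIELDS:
            if getattr(self, f) not in ("shared", "free"):
                raise ValueError(f"{f} must be 'shared' or 'free'")

    @property
    def n_free(self) -> int:
        n = len(self.conditions)
        return sum(1 if getattr(self, f) == "shared" else n
                   for f in PARAM_FIELDS)

    def unpack(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        """Expand a flat parameter vector into per-condition parameter dicts."""
        out: dict[str, dict[str, float]] = {c: {} for c in self.conditions}
        i = 0
        for f in PARAM_FIELDS:
            if getattr(self, f) == "shared":
                for c in self.conditions:
                    out[c][f] = theta[i]
                i += 1
            else:
                for c in self.conditions:
                    out[c][f] = theta[i]
                    i += 1
        return out

    def pack(self, values: dict[str, dict[str, float]]) -> np.ndarray:
        theta = []
        for f in PARAM_FIELDS:
            if getattr(self, f) == "shared":
                theta.append(np.mean([values[c][f] for c in self.conditions]))
            else:
                theta.extend(values[c][f] for c in self.conditions)
        return np.asarray(theta)


@dataclass
class FitResult:
    """Best-fitting parameters per condition plus fit diagnostics."""

    params: dict[str, DDMParams]
    design: FitDesign
    log_likelihood: float
    n_free: int
    n_trials: int
    bic: float
    n_starts: int
    start_loglik: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = {c: {f: getattr(p, f) for f in PARAM_FIELDS}
                for c, p in self.params.items()}
        return pd.DataFrame(rows).T


def bic(log_likelihood: float, n_free: int, n_trials: int) -> float:
    """Bayesian Information Criterion: k ln(n) - 2 logLik."""
    return n_free * np.log(n_trials) - 2.0 * log_likelihood


def _cell_summary(trials: pd.DataFrame, conditions, quantiles):
    """Per condition x choice: quantile bin edges and observed bin counts."""
    cells = {}
    for cond in conditions:
        sub = trials[trials["condition"] == cond]
        if len(sub) == 0:
            raise ValueError(f"no trials for condition {cond!r}")
        for choice in ("upper", "lower"):
            rts = np.sort(sub.loc[sub["choice"] == choice, "rt"].to_numpy())
            if len(rts) >= _MIN_CELL_FOR_QUANTILES:
                edges = np.quantile(rts, quantiles)
                counts = np.diff(np.searchsorted(
                    rts, np.concatenate(([0.0], edges, [np.inf]))))
                # searchsorted('left') puts ties below the edge into the upper
                # bin; recount exactly
                counts = np.histogram(
                    rts, np.concatenate(([0.0], edges, [np.inf])))[0]
            else:
                # too few trials for stable quantiles: collapse to one bin
                edges = np.array([])
                counts = np.array([len(rts)])
            cells[(cond, choice)] = (edges, counts)
    return cells


def _negloglik(theta, design: FitDesign, cells) -> float:
    values = design.unpack(np.asarray(theta, dtype=float))
    total = 0.0
    for cond in design.conditions:
        p = values[cond]
        a, z, t0 = p["threshold"], p["starting_point"], p["nondecision_t0"]
        if not (a > 0 and 0 < z < a and t0 >= 0):
            return _PENALTY * (1.0 + abs(min(a, 1e-3)) + abs(min(z, 0.0))
                               + abs(min(a - z, 0.0)) + abs(min(t0, 0.0)))
        params = DDMParams(p["drift"], a, z, t0)
        for choice in ("upper", "lower"):
            edges, counts = cells[(cond, choice)]
            p_choice = (choice_probability(params) if choice == "upper"
                        else 1.0 - choice_probability(params))
            if len(edges) == 0:
                probs = np.array([p_choice])
            else:
                cdf = first_passage_cdf(edges - t0, params, choice)
                probs = np.diff(np.concatenate(([0.0], cdf, [p_choice])))
            if (probs[counts > 0] <= 0).any():
                return _PENALTY
            mask = counts > 0
            total += float(counts[mask] @ np.log(probs[mask]))
    return -total


def ez_init(trials: pd.DataFrame, noise_s: float = DEFAULT_NOISE,
            ) -> dict[str, dict[str, float]]:
    """Method-of-moments (EZ-diffusion style) starting values per condition.

    Drift, boundary and non-decision time come from the EZ equations applied
    to upper-boundary proportion, mean and variance of RT; the starting point
    is then solved from the observed upper-choice fraction.
    """
    s2 = noise_s**2
    init = {}
    for cond, sub in trials.groupby("condition", sort=False):
        n = len(sub)
        p_up = np.clip(sub["choice"].eq("upper").mean(),
                       0.5 + 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        # EZ works on the dominant-boundary fraction; fold below-chance cases
        vrt = max(float(sub["rt"].var()), 1e-6)
        mrt = float(sub["rt"].mean())
        L = np.log(p_up / (1.0 - p_up))
        x = L * (L * p_up**2 - L * p_up + p_up - 0.5) / vrt
        v = np.sign(p_up - 0.5) * noise_s * x**0.25
        a = s2 * L / v
        mdt = (a / (2.0 * v)) * (1.0 - np.exp(-v * a / s2)) / \
            (1.0 + np.exp(-v * a / s2))
        t0 = max(mrt - mdt, 0.01)
        # starting point from the raw (unfolded) upper fraction
        p_raw = np.clip(sub["choice"].eq("upper").mean(), 0.02, 0.98)
        if abs(v) > 1e-6:
            arg = 1.0 - p_raw * (1.0 - np.exp(-2.0 * v * a / s2))
            z = (-s2 / (2.0 * v) * np.log(arg)
                 if arg > 0 else a / 2.0)
        else:
            z = p_raw * a
        z = float(np.clip(z, 0.15 * a, 0.85 * a))
        init[cond] = {"drift": float(v), "threshold": float(a),
                      "starting_point": z, "nondecision_t0": float(t0)}
    return init


def fit(trials: pd.DataFrame, design: FitDesign,
        quantiles=DEFAULT_QUANTILES, seed: int | None = None,
        n_starts: int = 10, perturb_sd: float = 0.15) -> FitResult:
    """Fit the pure DDM by quantile-multinomial maximum likelihood.

    Runs ``n_starts`` Nelder-Mead searches from method-of-moments starting
    values (the first unperturbed, the rest log-normally perturbed using
    ``seed``); the best final log-likelihood wins, ties broken by the smaller
    parameter-vector norm.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    missing = set(design.conditions) - set(trials["condition"].unique())
    if missing:
        raise ValueError(f"conditions absent from data: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cells = _cell_summary(trials, design.conditions, quantiles)
    theta0 = design.pack(ez_init(trials[trials["condition"]
                                        .isin(design.conditions)]))

    best = None
    start_nll = np.full(n_starts, np.nan)
    for i in range(n_starts):
        start = theta0 if i == 0 else theta0 * rng.lognormal(
            0.0, perturb_sd, size=theta0.size)
        res = minimize(_negloglik, start, args=(design, cells),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 4000 * theta0.size,
                                "maxfev": 4000 * theta0.size})
        start_nll[i] = res.fun
        if res.fun >= _PENALTY:
            continue
        if (best is None or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9
                    and np.linalg.norm(res.x) < np.linalg.norm(best.x))):
            best = res
    if best is None:
        raise RuntimeError(
            "optimizer failed from every start; final objective values: "
            f"{start_nll!r}")

    values = design.unpack(best.x)
    params = {c: DDMParams(**values[c]) for c in design.conditions}
    n_trials = int(trials["condition"].isin(design.conditions).sum())
    ll = -float(best.fun)
    return FitResult(params=params, design=design, log_likelihood=ll,
                     n_free=design.n_free, n_trials=n_trials,
                     bic=bic(ll, design.n_free, n_trials),
                     n_starts=n_starts, start_loglik=-start_nll)
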