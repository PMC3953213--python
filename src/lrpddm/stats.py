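"""Cross-subject statistics linking LRP measures to DDM parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["RobustFit", "robust_regress", "within_subject_slope_test",
           "paired_area_test"]

#: standard 95%-efficiency tuning constant for the bisquare psi function
BISQUARE_C = 4.685


@dataclass
class RobustFit:
    slope: float
    intercept: float
    t: float
    p: float
    weights: np.ndarray


def robust_regress(x, y) -> RobustFit:
    """Robust line fit by IRLS with Tukey bisquare weights.

    On outlier-free data this coincides with OLS; gross outliers are
    down-weighted to (near) zero.  The t/p refer to the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid_scale = float(np.std(ols.resid))
    if resid_scale < 1e-12 * max(float(np.std(y)), 1.0):
        # perfect linear fit: IRLS scale degenerates, but the answer is OLS
        return RobustFit(slope=float(ols.params[1]),
                         intercept=float(ols.params[0]),
                         t=float(ols.tvalues[1]), p=float(ols.pvalues[1]),
                         weights=np.ones_like(x))
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    res = model.fit()
    return RobustFit(slope=float(res.params[1]),
                     intercept=float(res.params[0]),
                     t=float(res.tvalues[1]), p=float(res.pvalues[1]),
                     weights=np.asarray(res.weights))


def within_subject_slope_test(pairs: dict) -> tuple[float, int, float]:
    """One-sample t-test on per-subject OLS slopes against zero.

    ``pairs`` maps subject -> (x, y) arrays over that subject's conditions.
    Subjects with fewer than two distinct conditions are dropped with a
    warning.  Returns (t, df, two-sided p).
    """
    import warnings
    slopes = []
    for subj, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2 or np.ptp(x) == 0:
            warnings.warn(f"subject {subj!r} has <2 usable conditions; dropped")
            continue
        slopes.append(np.polyfit(x, y, 1)[0])
    if len(slopes) < 2:
        raise ValueError("need at least two subjects with valid slopes")
    t, p = sps.ttest_1samp(slopes, 0.0)
    return float(t), len(slopes) - 1, float(p)


def paired_area_test(areas_a, areas_b) -> tuple[float, float]:
    """Paired t-test on per-subject area measures (e.g. preferred vs
    non-preferred windows).

    A degenerate case with zero variance of the differences but a nonzero
    mean is reported as (inf with the sign of the mean, p = 0.0).
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size != b.size:
        raise ValueError("subjects are not matched")
    if a.size < 2:
        raise ValueError("need at least two subjects")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)
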