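"""Specific growth-rate estimation and many-to-one group comparison.

The specific growth rate mu (per hour) is the least-squares slope of
ln(OD600) versus time over an exponential-phase window; when no window is
given, the contiguous sub-window (>= 4 points) maximising R^2 is chosen
automatically.  Group comparisons follow one-way ANOVA with Dunnett's
many-to-one test against the control: adjusted p-values are computed from
the equicorrelated multivariate-t distribution of the simultaneous
t-statistics, evaluated by seeded Monte-Carlo integration, so arbitrary
group counts need no critical-value tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (DegenerateDataError, InsufficientDataError,
                     InvalidArgumentError)
from .synthetic_data import ODSeries


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu: float                       # per hour
    intercept: float                # ln OD at t=0 of the fit
    window: tuple                   # (t_start, t_end) used
    r_squared: float
    residual_se: float
    n_points: int


def _linfit(t: np.ndarray, y: np.ndarray):
    res = sps.linregress(t, y)
    n = len(t)
    resid = y - (res.intercept + res.slope * t)
    rse = float(np.sqrt(np.sum(resid ** 2) / (n - 2))) if n > 2 else 0.0
    return res.slope, res.intercept, res.rvalue ** 2, rse


def specific_growth_rate(series: ODSeries,
                         window: Optional[tuple] = None,
                         min_points: int = 4) -> GrowthRateEstimate:
    """Slope of ln(OD600) vs time = specific growth rate mu.

    With an explicit (t_start, t_end) window only points inside it are
    fitted (>= 3 required); otherwise the contiguous sub-window of at least
    ``min_points`` points with maximal R^2 is selected.
    """
    t = np.asarray(series.times, dtype=float)
    od = np.asarray(series.od600, dtype=float)
    if np.any(od <= 0):
        raise InvalidArgumentError("OD600 must be positive for a log fit")
    y = np.log(od)

    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        if m.sum() < 3:
            raise InsufficientDataError("window holds fewer than 3 points")
        slope, icpt, r2, rse = _linfit(t[m], y[m])
        return GrowthRateEstimate(float(slope), float(icpt),
                                  (float(t[m][0]), float(t[m][-1])),
                                  float(r2), rse, int(m.sum()))

    n = len(t)
    if n < 3:
        raise InsufficientDataError("need >= 3 points")
    min_points = min(min_points, n)
    best = None
    for i in range(0, n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, icpt, r2, rse = _linfit(t[i:j], y[i:j])
            # prefer higher R^2; among ties (e.g. exact exponential), the
            # longest window
            key = (round(r2, 12), j - i)
            if best is None or key > best[0]:
                best = (key, slope, icpt, r2, rse, (t[i], t[j - 1]), j - i)
    _, slope, icpt, r2, rse, win, k = best
    return GrowthRateEstimate(float(slope), float(icpt),
                              (float(win[0]), float(win[1])), float(r2),
                              rse, int(k))


# --------------------------------------------------------------------------- #
# ANOVA + Dunnett many-to-one comparison
# --------------------------------------------------------------------------- #


@dataclass
class GroupComparison:
    control: str
    group_means: dict
    group_sds: dict
    group_ns: dict
    anova_f: float
    anova_p: float
    t_statistics: dict              # per non-control group
    raw_p: dict                     # unadjusted two-sided p (pooled t)
    adjusted_p: dict                # Dunnett-adjusted
    stars: dict = field(default_factory=dict)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def dunnett_max_abs_t_sample(ns: Sequence[int], n_control: int, df: int,
                             n_mc: int, rng: np.random.Generator
                             ) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    The simultaneous t-statistics are equicorrelated multivariate t with
    correlations rho_ij = lambda_i lambda_j, lambda_i =
    sqrt(n_i / (n_i + n0)); the factor structure Z_i = lambda_i Z0 +
    sqrt(1 - lambda_i^2) e_i makes the draw O(k) per replicate.
    """
    lam = np.sqrt(np.asarray(ns, dtype=float)
                  / (np.asarray(ns, dtype=float) + n_control))
    z0 = rng.standard_normal(n_mc)
    eps = rng.standard_normal((n_mc, len(lam)))
    z = z0[:, None] * lam[None, :] + eps * np.sqrt(1 - lam ** 2)[None, :]
    chi = rng.chisquare(df, n_mc) / df
    t = z / np.sqrt(chi)[:, None]
    return np.abs(t).max(axis=1)


def compare_growth_dunnett(groups: Mapping[str, Sequence[float]],
                           control: str, n_mc: int = 100_000,
                           seed: int = 0) -> GroupComparison:
    """One-way ANOVA followed by Dunnett's test of every group vs control.

    Two-sided adjusted p-values are P(max_i |T_i| >= |t_k|) under the joint
    null, estimated from ``n_mc`` seeded Monte-Carlo draws of the
    equicorrelated multivariate-t.  Significance stars at 0.05/0.01/0.001.
    """
    if control not in groups:
        raise InvalidArgumentError(f"control group {control!r} missing")
    names = [g for g in groups if g != control]
    if not names:
        raise InvalidArgumentError("need at least one comparison group")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrs.items():
        if len(a) < 2:
            raise InvalidArgumentError(f"group {g!r} needs >= 2 replicates")

    k = len(arrs)
    N = sum(len(a) for a in arrs.values())
    df = N - k
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    if sse <= 0:
        raise DegenerateDataError("zero within-group variance in all groups")
    s2 = sse / df

    anova_f, anova_p = sps.f_oneway(*arrs.values())

    ctrl = arrs[control]
    n0 = len(ctrl)
    tstats = {}
    raw = {}
    for g in names:
        a = arrs[g]
        se = np.sqrt(s2 * (1 / len(a) + 1 / n0))
        t = (a.mean() - ctrl.mean()) / se
        tstats[g] = float(t)
        raw[g] = float(2 * sps.t.sf(abs(t), df))

    rng = np.random.default_rng(seed)
    ns = [len(arrs[g]) for g in names]
    max_t = dunnett_max_abs_t_sample(ns, n0, df, n_mc, rng)
    adj = {}
    for g in names:
        p = float(np.mean(max_t >= abs(tstats[g])))
        adj[g] = max(p, raw[g])  # adjusted p can never fall below raw p

    return GroupComparison(
        control=control,
        group_means={g: float(a.mean()) for g, a in arrs.items()},
        group_sds={g: float(a.std(ddof=1)) for g, a in arrs.items()},
        group_ns={g: int(len(a)) for g, a in arrs.items()},
        anova_f=float(anova_f), anova_p=float(anova_p),
        t_statistics=tstats, raw_p=raw, adjusted_p=adj,
        stars={g: _stars(p) for g, p in adj.items()},
    )
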