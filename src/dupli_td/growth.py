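"""Logistic growth-curve fitting and serial-transfer generation arithmetic.

OD600 time series are fitted to the logistic model
``N(t) = K / (1 + ((K - N0)/N0) exp(-r t))``; the intrinsic rate r is reported
as the maximum growth rate (mu_max, h^-1) and K as the carrying capacity,
matching the conventions of standard microbial growth-curve tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError
from .simulate import logistic
from .td import compare_groups_ranksum

__all__ = [
    "GrowthFit",
    "LogisticGrowthModel",
    "fit_logistic",
    "compare_growth",
    "generations_from_bottleneck",
    "fit_od_table",
]

logger = logging.getLogger(__name__)

OD_FLOOR = 1e-4  # OD600 floor before log operations


@dataclass
class GrowthFit:
    """Fitted logistic parameters for one well/population.

    K: carrying capacity (OD600); r: intrinsic growth rate, reported as
    mu_max (h^-1); N0: initial population size (OD600); residual_sd: root
    mean squared residual; converged: whether the fit succeeded with
    K > N0 > 0 and r > 0.
    """

    K: float
    r: float
    N0: float
    residual_sd: float
    converged: bool

    @property
    def mu_max(self) -> float:
        return self.r

    def summary(self) -> str:
        if not self.converged:
            return "logistic fit: did not converge (parameters withheld)"
        return (
            "logistic fit\n"
            f"  mu_max (r):       {self.r:.4f} h^-1\n"
            f"  carry capacity K: {self.K:.4f} OD600\n"
            f"  N0:               {self.N0:.4g} OD600\n"
            f"  residual sd:      {self.residual_sd:.4g}"
        )


def _initial_guess(t: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    K0 = float(od.max())
    N0 = float(od[od > 0][0]) if (od > 0).any() else OD_FLOOR
    # slope of log OD over the early quartile of the time range
    t_cut = t.min() + 0.25 * (t.max() - t.min())
    early = t <= t_cut
    if early.sum() < 2:
        early = np.zeros_like(t, dtype=bool)
        early[: max(2, len(t) // 4)] = True
    y = np.log(np.maximum(od[early], OD_FLOOR))
    slope = np.polyfit(t[early], y, 1)[0]
    r0 = float(slope) if slope > 0 else 0.1
    return K0, r0, N0


def fit_logistic(times, od, blank: float | np.ndarray | None = None) -> GrowthFit:
    """Least-squares logistic fit of an OD600 series.

    ``blank`` (a scalar or per-point baseline) is subtracted first; values are
    floored at a small positive constant. A fit that fails to converge, or
    converges to parameters violating K > N0 > 0 or r > 0, is returned with
    ``converged=False`` and NaN parameters.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.size < 5:
        raise InputError("need >= 5 matching time/OD points")
    if blank is not None:
        y = y - blank
    y = np.maximum(y, OD_FLOOR)

    K0, r0, N00 = _initial_guess(t, y)
    failed = GrowthFit(K=float("nan"), r=float("nan"), N0=float("nan"),
                       residual_sd=float("nan"), converged=False)
    try:
        popt, _ = curve_fit(
            logistic,
            t,
            y,
            p0=(max(K0, 2 * OD_FLOOR), r0, min(N00, K0 * 0.99)),
            bounds=((OD_FLOOR, 1e-6, OD_FLOOR / 10), (np.inf, np.inf, np.inf)),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError):
        return failed
    K, r, N0 = (float(v) for v in popt)
    if not (K > N0 > 0 and r > 0) or not all(map(math.isfinite, (K, r, N0))):
        return failed
    resid = y - logistic(t, K, r, N0)
    # a "fit" that explains nothing beyond a flat line is not growth
    if np.var(y) <= (OD_FLOOR * 10) ** 2:
        return failed
    return GrowthFit(K=K, r=r, N0=N0, residual_sd=float(np.sqrt(np.mean(resid**2))),
                     converged=True)


class LogisticGrowthModel:
    """Model object for one OD600 series; ``fit()`` returns a :class:`GrowthFit`."""

    def __init__(self, times, od, blank=None):
        self.times = np.asarray(times, dtype=float)
        self.od = np.asarray(od, dtype=float)
        self.blank = blank

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col="time_h", od_col="od600", blank=None):
        df = df.sort_values(time_col)
        return cls(df[time_col].to_numpy(), df[od_col].to_numpy(), blank=blank)

    def fit(self) -> GrowthFit:
        return fit_logistic(self.times, self.od, blank=self.blank)


def fit_od_table(
    od: pd.DataFrame,
    blank_group: str | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Fit every well of a long OD table (well, [group,] time_h, od600).

    If ``blank_group`` names a value of ``group_col``, the mean of those
    uninoculated control wells (per time point) is subtracted from every other
    well before fitting.
    """
    blank = None
    if blank_group is not None and group_col in od.columns:
        ctrl = od[od[group_col] == blank_group]
        if ctrl.empty:
            raise InputError(f"no wells in blank group {blank_group!r}")
        blank_by_t = ctrl.groupby("time_h")["od600"].mean()
        od = od[od[group_col] != blank_group]
    rows = []
    for well, grp in od.groupby("well"):
        grp = grp.sort_values("time_h")
        b = blank_by_t.reindex(grp["time_h"]).to_numpy() if blank_group else None
        fit = fit_logistic(grp["time_h"].to_numpy(), grp["od600"].to_numpy(), blank=b)
        row = {"well": well, "K": fit.K, "mu_max": fit.r, "N0": fit.N0,
               "residual_sd": fit.residual_sd, "converged": fit.converged}
        if group_col in grp.columns:
            row["group"] = grp[group_col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_growth(groups: dict[str, list[GrowthFit]]) -> pd.DataFrame:
    """Rank-sum comparison of mu_max and K between every pair of fit groups.

    Non-converged fits are excluded (and counted in the output); each row
    reports the two-sided Wilcoxon-Mann-Whitney p and group medians for one
    parameter and one group pair.
    """
    clean: dict[str, list[GrowthFit]] = {}
    excluded: dict[str, int] = {}
    for name, fits in groups.items():
        ok = [f for f in fits if f.converged]
        excluded[name] = len(fits) - len(ok)
        if excluded[name]:
            logger.warning("group %s: excluded %d non-converged fit(s)", name, excluded[name])
        if len(ok) < 2:
            raise InputError(f"group {name!r} has fewer than 2 converged fits")
        clean[name] = ok
    names = list(clean)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            for param, getter in (("mu_max", lambda f: f.r), ("K", lambda f: f.K)):
                va = [getter(f) for f in clean[ga]]
                vb = [getter(f) for f in clean[gb]]
                p, med_a, med_b = compare_groups_ranksum(va, vb)
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "parameter": param,
                        "p": p,
                        "median_a": med_a,
                        "median_b": med_b,
                        "excluded_a": excluded[ga],
                        "excluded_b": excluded[gb],
                    }
                )
    return pd.DataFrame(rows)


def generations_from_bottleneck(n_passages: int, bottleneck_fraction: float) -> tuple[float, int]:
    """Doublings implied by serial transfer: passages x log2(1 / fraction).

    Returns (raw, rounded); values >= 100 are rounded to two significant
    figures (660 for 664.4), smaller ones to the nearest integer (33 for
    33.2).
    """
    if not 0 < bottleneck_fraction < 1:
        raise InputError("bottleneck_fraction must lie in (0, 1)")
    if n_passages < 0:
        raise InputError("n_passages must be >= 0")
    raw = n_passages * math.log2(1.0 / bottleneck_fraction)
    if raw >= 100:
        mag = 10 ** (math.floor(math.log10(raw)) - 1)
        rounded = int(round(raw / mag) * mag)
    else:
        rounded = int(round(raw))
    return raw, rounded
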