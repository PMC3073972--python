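"""Insect bioassay analytics.

Replicate mortality summaries, Abbott control-corrected mortality, probit
dose-response regression with LC50 and 95% fiducial limits (Fieller's
theorem, with a heterogeneity factor when the fit over-disperses), and
egg-hatch summaries.

The probit model: observed mortality proportion p at dose d satisfies

    probit(p) = intercept + slope * log10(d)

so LC50 = 10^(-intercept/slope). Control (natural) mortality is removed
before fitting by Abbott's correction using the dose-0 control row,
matching the corrected-mortality workflow of classical spray bioassays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

__all__ = [
    "MortalitySummary",
    "DoseResponseFit",
    "mortality_percent",
    "abbott_corrected",
    "probit_fit",
    "hatch_ratio",
]


@dataclass
class MortalitySummary:
    """Mean +/- sample sd of per-replicate percentages, report-rounded."""

    mean: float
    sd: float
    n_replicates: int
    sd_defined: bool  # False with a single replicate (sd reported as 0)

    def __str__(self) -> str:
        return f"{self.mean:.2f}±{self.sd:.2f}"


def _percent_summary(percents: Sequence[float]) -> MortalitySummary:
    arr = np.asarray(percents, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate is required")
    mean = round_half_up(float(arr.mean()), 2)
    if arr.size == 1:
        return MortalitySummary(mean=mean, sd=0.0, n_replicates=1, sd_defined=False)
    sd = round_half_up(float(arr.std(ddof=1)), 2)
    return MortalitySummary(mean=mean, sd=sd, n_replicates=arr.size, sd_defined=True)


def mortality_percent(
    dead: Sequence[int], n_insects: Sequence[int] | int
) -> MortalitySummary:
    """Replicate mortality percentages summarised as mean +/- sd (n-1)."""
    dead = np.asarray(dead, dtype=float)
    n = np.broadcast_to(np.asarray(n_insects, dtype=float), dead.shape)
    if np.any(n <= 0):
        raise ValueError("n_insects must be positive")
    if np.any(dead > n):
        raise ValueError("dead cannot exceed n_insects")
    return _percent_summary(dead / n * 100)


def hatch_ratio(
    hatched: Sequence[int], totals: Sequence[int] | int
) -> MortalitySummary:
    """Egg-hatch percentages summarised as mean +/- sd (n-1)."""
    hatched = np.asarray(hatched, dtype=float)
    n = np.broadcast_to(np.asarray(totals, dtype=float), hatched.shape)
    if np.any(n <= 0):
        raise ValueError("egg totals must be positive")
    return _percent_summary(hatched / n * 100)


def abbott_corrected(
    raw_pct: float, control_pct: float, ndigits: int | None = 2
) -> float:
    """Abbott's control correction: (T - C) / (100 - C) * 100.

    Removes background mortality C (%) from treatment mortality T (%).
    Negative corrected values (treatment below control) are clamped to 0
    with a warning. ``ndigits=None`` returns the unrounded value.
    """
    if not (0 <= raw_pct <= 100 and 0 <= control_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if control_pct >= 100:
        raise ValueError("control mortality of 100% leaves nothing to correct")
    value = (raw_pct - control_pct) / (100 - control_pct) * 100
    if value < 0:
        warnings.warn(
            f"treatment mortality {raw_pct} below control {control_pct}; clamped to 0",
            stacklevel=2,
        )
        value = 0.0
    return value if ndigits is None else round_half_up(value, ndigits)


@dataclass
class DoseResponseFit:
    """Probit regression result on log10(dose)."""

    slope: float
    intercept: float
    lc50: float
    ci95: tuple[float, float]
    converged: bool
    deviance: float
    df_resid: int
    heterogeneity: float          # max(1, deviance/df)
    fieller_g: float
    fieller_valid: bool           # False => ci95 is a delta-method interval
    control_mortality: float      # proportion used for Abbott pre-correction


def _probit_irls(
    x: np.ndarray, p: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted probit GLM via statsmodels IRLS.

    Returns (params [intercept, slope], covariance, deviance).
    """
    import statsmodels.api as sm

    X = sm.add_constant(x)
    model = sm.GLM(
        p, X, family=sm.families.Binomial(link=sm.families.links.Probit()),
        var_weights=w,
    )
    res = model.fit(tol=1e-12, maxiter=200)
    return np.asarray(res.params), np.asarray(res.cov_params()), float(res.deviance)


def probit_fit(
    doses: Sequence[float],
    n: Sequence[int],
    dead: Sequence[float],
    control_handling: str = "abbott",
) -> DoseResponseFit:
    """Fit a probit dose-mortality model and estimate LC50.

    Parameters
    ----------
    doses, n, dead : parallel arrays; a dose-0 row, when present, is the
        untreated control. With ``control_handling="abbott"`` the control
        mortality is removed from every positive-dose proportion by
        Abbott's correction before fitting; with ``"none"`` proportions
        are fitted as observed.

    The 95% limits on LC50 come from Fieller's theorem on the ratio
    -intercept/slope; when the fit is over-dispersed (deviance/df > 1)
    the covariance is inflated by the heterogeneity factor and the normal
    critical value is replaced by Student's t. When Fieller's g >= 1 the
    interval is undefined and a delta-method interval is returned with
    ``fieller_valid=False``.
    """
    if control_handling not in ("abbott", "none"):
        raise ValueError(f"unknown control_handling: {control_handling!r}")
    doses = np.asarray(doses, dtype=float)
    n = np.asarray(n, dtype=float)
    dead = np.asarray(dead, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    if np.any(dead > n) or np.any(dead < 0):
        raise ValueError("dead counts must lie in [0, n]")

    ctrl_mask = doses == 0
    control_p = float(dead[ctrl_mask].sum() / n[ctrl_mask].sum()) if ctrl_mask.any() else 0.0

    pos = ~ctrl_mask
    d = doses[pos]
    p = dead[pos] / n[pos]
    w = n[pos]
    if control_handling == "abbott" and control_p > 0:
        p = np.clip((p - control_p) / (1 - control_p), 0.0, 1.0)

    if len(np.unique(d)) < 2:
        raise ValueError("at least two distinct positive doses are required")
    if np.all(p <= 0) or np.all(p >= 1):
        raise ValueError("degenerate response: no dose-mortality gradient to fit")

    x = np.log10(d)
    params, cov, deviance = _probit_irls(x, p, w)
    intercept, slope = params
    if slope <= 0:
        raise ValueError(f"non-monotone dose response: fitted slope {slope:.4g} <= 0")

    df_resid = len(d) - 2
    h = max(1.0, deviance / df_resid) if df_resid > 0 else 1.0
    if h > 1.0 and df_resid > 0:
        cov = cov * h
        tcrit = float(stats.t.ppf(0.975, df_resid))
    else:
        tcrit = float(stats.norm.ppf(0.975))

    m = -intercept / slope            # log10 LC50
    vaa, vab, vbb = cov[0, 0], cov[0, 1], cov[1, 1]
    # Fieller on m = -a/b: variance terms of (a + b*m)
    g = tcrit**2 * vbb / slope**2
    if g < 1:
        centre = m + (g / (1 - g)) * (m + vab / vbb)
        disc = vaa + 2 * m * vab + m**2 * vbb - g * (vaa - vab**2 / vbb)
        half = (tcrit / (slope * (1 - g))) * np.sqrt(max(disc, 0.0))
        lo, hi = centre - half, centre + half
        fieller_valid = True
    else:
        # delta method fallback
        var_m = (vaa + 2 * m * vab + m**2 * vbb) / slope**2
        half = tcrit * np.sqrt(max(var_m, 0.0))
        lo, hi = m - half, m + half
        fieller_valid = False

    return DoseResponseFit(
        slope=float(slope),
        intercept=float(intercept),
        lc50=float(10**m),
        ci95=(float(10**lo), float(10**hi)),
        converged=True,
        deviance=deviance,
        df_resid=df_resid,
        heterogeneity=h,
        fieller_g=float(g),
        fieller_valid=fieller_valid,
        control_mortality=control_p,
    )
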