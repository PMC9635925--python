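"""Dose-response fitting and degranulation statistics.

Potency of an agonist is summarized by the four-parameter logistic (4PL, or
Hill) curve in log10 molar concentration x:

    y(x) = bottom + (top - bottom) / (1 + 10^((log_ec50 - x) * hill))

EC50 is the midpoint concentration (10^log_ec50); ``hill`` sets the steepness
and sign of the response.  Fits are deterministic nonlinear least squares
with a multi-start over initial midpoints to avoid local minima, and genotype
comparisons (wild-type vs N62S mutant) are z-tests on the fitted log_ec50
difference.

Mast-cell degranulation is quantified as percent beta-hexosaminidase release
(supernatant over total), and the genotype dependence of release is tested by
two-way fixed-effects ANOVA (condition x genotype) with Sidak-adjusted
per-condition genotype contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LOG10_CONCENTRATIONS",
    "DoseResponseFit",
    "EC50Comparison",
    "GenotypeEffectReport",
    "four_pl",
    "fit_dose_response",
    "compare_ec50",
    "percent_release",
    "sidak_adjust",
    "genotype_effect_test",
]

#: The assay's 8-point concentration grid (log10 molar, half-log steps).
DEFAULT_LOG10_CONCENTRATIONS = (-6.5, -6.0, -5.5, -5.0, -4.5, -4.0, -3.5, -3.0)


def four_pl(x, bottom: float, top: float, log_ec50: float, hill: float):
    """Four-parameter logistic response at log10 concentration ``x``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        y = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))
    return y if y.ndim else float(y)


@dataclass
class DoseResponseFit:
    """4PL least-squares fit for one compound x cell line."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    se_log_ec50: float
    rss: float
    n_points: int
    converged: bool
    degenerate: bool = False
    extrapolated: bool = False

    @property
    def ec50(self) -> float:
        """EC50 in molar units."""
        return 10.0 ** self.log_ec50


def _coerce_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        xcol = cols.get("log10_conc_m") or cols.get("x")
        ycol = cols.get("response") or cols.get("y")
        if xcol is None or ycol is None:
            raise ValueError("need columns log10_conc_M/response (or x/y)")
        x = data[xcol].to_numpy(dtype=float)
        y = data[ycol].to_numpy(dtype=float)
    else:
        x, y = data
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fit_dose_response(data) -> DoseResponseFit:
    """Fit the 4PL to (log10 concentration, response) measurements.

    ``data`` is a DataFrame with columns ``log10_conc_M`` and ``response``
    (replicate rows enter as individual points) or an ``(x, y)`` pair of
    arrays.  The fit multi-starts over a grid of initial midpoints spanning
    the tested range and over both response directions, and keeps the
    lowest-RSS solution; it is deterministic given the data.  The standard
    error of log_ec50 comes from the curvature of the fit.  If no start
    converges the best attempt is returned with ``converged=False``.
    """
    x, y = _coerce_xy(data)
    if np.unique(x).size < 4:
        raise ValueError("fit_dose_response needs >= 4 distinct concentrations")
    ymin, ymax = float(y.min()), float(y.max())
    span = ymax - ymin
    starts_mid = np.linspace(x.min(), x.max(), 5)
    best = None
    for le0 in starts_mid:
        for h0 in (1.0, -1.0):
            p0 = [ymin, ymax, le0, h0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = scipy.optimize.curve_fit(
                        four_pl, x, y, p0=p0, maxfev=20000
                    )
            except (RuntimeError, scipy.optimize.OptimizeWarning):
                continue
            rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, popt, pcov)
    if best is None:
        # no start converged; report the flat-curve baseline attempt
        popt = np.array([ymin, ymax, float(np.median(x)), 1.0])
        rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
        return DoseResponseFit(
            bottom=popt[0], top=popt[1], log_ec50=popt[2], hill=popt[3],
            se_log_ec50=float("nan"), rss=rss, n_points=x.size,
            converged=False, degenerate=True,
        )
    rss, popt, pcov = best
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if bottom > top:  # canonical orientation; the curve itself is unchanged
        bottom, top = top, bottom
        hill = -hill
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    degenerate = abs(hill) < 1e-6 or (top - bottom) < 1e-9 * max(1.0, abs(span))
    if degenerate:
        log.warning("fit_dose_response: degenerate fit (flat curve)")
    extrapolated = not (x.min() <= log_ec50 <= x.max())
    if extrapolated:
        log.warning("fit_dose_response: EC50 outside the tested range")
    return DoseResponseFit(
        bottom=bottom, top=top, log_ec50=log_ec50, hill=hill,
        se_log_ec50=se, rss=rss, n_points=int(x.size),
        converged=True, degenerate=degenerate, extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class EC50Comparison:
    """Genotype shift in potency: MUT minus WT on the log10 EC50 scale."""

    diff_log_ec50: float
    se_diff: float
    z: float
    p_value: float
    fold_change: float  # ec50_mut / ec50_wt


def compare_ec50(fit_wt: DoseResponseFit, fit_mut: DoseResponseFit) -> EC50Comparison:
    """z-test on the difference of fitted log_ec50 values.

    The fold change is EC50(MUT)/EC50(WT); a loss-of-function mutation
    shifts it above 1.  Both fits must have converged.
    """
    if not (fit_wt.converged and fit_mut.converged):
        raise ValueError("compare_ec50 requires converged fits")
    diff = fit_mut.log_ec50 - fit_wt.log_ec50
    se = float(np.sqrt(fit_wt.se_log_ec50 ** 2 + fit_mut.se_log_ec50 ** 2))
    z = diff / se if se > 0 else (0.0 if diff == 0 else float("inf") * np.sign(diff))
    p = 2.0 * scipy.stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    if z == 0:
        p = 1.0
    return EC50Comparison(
        diff_log_ec50=float(diff),
        se_diff=se,
        z=float(z),
        p_value=float(p),
        fold_change=float(10.0 ** diff),
    )


def percent_release(supernatant_signal: float, lysate_signal: float) -> float:
    """Percent of total beta-hexosaminidase released into the supernatant."""
    if supernatant_signal < 0 or lysate_signal < 0:
        raise ValueError("signals must be non-negative")
    total = supernatant_signal + lysate_signal
    if total == 0:
        raise ValueError("supernatant + lysate must be > 0")
    return 100.0 * supernatant_signal / total


def sidak_adjust(p: float, m: int) -> float:
    """Sidak correction of one of ``m`` simultaneous comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - min(p, 1.0)) ** m))


@dataclass
class GenotypeEffectReport:
    """Two-way ANOVA table plus Sidak-adjusted per-condition contrasts."""

    anova: pd.DataFrame
    contrasts: pd.DataFrame
    residual_df: float
    mse: float


def genotype_effect_test(samples: pd.DataFrame) -> GenotypeEffectReport:
    """Two-way fixed-effects ANOVA of percent release.

    ``samples`` needs columns ``condition``, ``genotype`` and
    ``percent_release`` with exactly two genotypes, every condition x
    genotype cell present with n >= 2.  The report carries the ANOVA table
    (condition, genotype, interaction) and one genotype contrast per
    condition, Sidak-adjusted for the number of conditions.  A table with
    zero variance everywhere yields F = 0 and p = 1 by convention.
    """
    required = {"condition", "genotype", "percent_release"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = samples[["condition", "genotype", "percent_release"]].copy()
    df["percent_release"] = df["percent_release"].astype(float)
    genotypes = sorted(df["genotype"].unique())
    conditions = sorted(df["condition"].unique())
    if len(genotypes) != 2:
        raise ValueError(f"need exactly 2 genotypes, got {genotypes}")
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    counts = df.groupby(["condition", "genotype"]).size()
    missing_cells = [
        (c, g)
        for c in conditions
        for g in genotypes
        if counts.get((c, g), 0) < 2
    ]
    if missing_cells:
        raise ValueError(f"cells missing or with n < 2: {missing_cells}")

    y = df["percent_release"].to_numpy()
    n_cells = len(conditions) * len(genotypes)
    residual_df = float(len(df) - n_cells)

    if np.ptp(y) == 0.0:
        # no variance anywhere: all effects vanish, nothing to test
        anova = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [len(conditions) - 1, 1, len(conditions) - 1, residual_df],
                "F": [0.0, 0.0, 0.0, np.nan],
                "PR(>F)": [1.0, 1.0, 1.0, np.nan],
            },
            index=["C(condition)", "C(genotype)", "C(condition):C(genotype)", "Residual"],
        )
        contrasts = pd.DataFrame(
            {
                "condition": conditions,
                "diff": 0.0,
                "se": 0.0,
                "t": 0.0,
                "p_raw": 1.0,
                "p_sidak": 1.0,
            }
        )
        return GenotypeEffectReport(anova=anova, contrasts=contrasts,
                                    residual_df=residual_df, mse=0.0)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("percent_release ~ C(condition) * C(genotype)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)

    rows = []
    g0, g1 = genotypes
    for cond in conditions:
        a = df.loc[(df["condition"] == cond) & (df["genotype"] == g0), "percent_release"]
        b = df.loc[(df["condition"] == cond) & (df["genotype"] == g1), "percent_release"]
        diff = float(a.mean() - b.mean())
        se = float(np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b))))
        if se == 0:
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        else:
            t = diff / se
        p_raw = float(2.0 * scipy.stats.t.sf(abs(t), model.df_resid)) if np.isfinite(t) else 0.0
        rows.append(
            {
                "condition": cond,
                "diff": diff,
                "se": se,
                "t": float(t),
                "p_raw": p_raw,
                "p_sidak": sidak_adjust(p_raw, len(conditions)),
            }
        )
    contrasts = pd.DataFrame(rows)
    return GenotypeEffectReport(
        anova=anova, contrasts=contrasts,
        residual_df=float(model.df_resid), mse=mse,
    )
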