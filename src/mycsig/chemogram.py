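"""Dose-response analysis of organoid drug screens (chemograms).

Raw plate signals are normalized to percent of the vehicle wells, fitted per
(sample, drug) with a four-parameter log-logistic model

    viability(d) = bottom + (top - bottom) / (1 + (d / IC50)**hill)

using robust (soft-L1) nonlinear least squares with multi-start
initialization, and summarized as IC50 and total AUC — the trapezoidal area
of the mean viability against log10 dose over the observed positive-dose
range.  Lower AUC means greater drug sensitivity.  Group-level contrasts
between MYC-high and MYC-low samples use the Mann-Whitney U test, with a
Welch t-test reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "normalize_viability",
    "fit_dose_response",
    "fit_table",
    "compute_auc",
    "compare_groups",
    "cross_drug_correlation",
]

VIABILITY_COLUMNS = ["sample", "drug", "dose_uM", "replicate"]


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted log-logistic parameters and sensitivity summaries.

    ``ic50`` is in µM (NaN when the fit is unconstrained), ``auc`` in
    percent x log10-µM units, ``residual_scale`` is the RMS residual of the
    converged fit.
    """

    sample: str
    drug: str
    top: float
    bottom: float
    log10_ic50: float
    hill: float
    ic50: float
    auc: float
    converged: bool
    residual_scale: float

    def __post_init__(self) -> None:
        if self.converged:
            if self.bottom > self.top + 1e-9:
                raise ValueError("bottom must not exceed top in a converged fit")
            if not self.ic50 > 0:
                raise ValueError("converged fit requires positive IC50")
        if not (math.isnan(self.auc) or self.auc >= 0):
            raise ValueError("auc must be non-negative")


def _check_viability_table(t: pd.DataFrame, value_col: str) -> None:
    missing = [c for c in VIABILITY_COLUMNS + [value_col] if c not in t.columns]
    if missing:
        raise ValueError(f"viability table lacks column(s): {missing}")
    if (t["dose_uM"] < 0).any():
        raise ValueError("doses must be non-negative")


def normalize_viability(t: pd.DataFrame, signal_col: str = "signal") -> pd.DataFrame:
    """Express raw signals as percent of the vehicle (dose 0) mean.

    Per (sample, drug), viability_pct = 100 * signal / mean(vehicle signal).
    Vehicle rows are retained at their normalized values.
    """
    _check_viability_table(t, signal_col)
    out = t.copy()
    out["viability_pct"] = np.nan
    for (sample, drug), grp in out.groupby(["sample", "drug"], sort=False):
        vehicle = grp.loc[grp["dose_uM"] == 0, signal_col]
        if vehicle.empty or not vehicle.mean() > 0:
            raise ValueError(
                f"missing or non-positive vehicle wells for sample {sample!r}, drug {drug!r}"
            )
        out.loc[grp.index, "viability_pct"] = 100.0 * grp[signal_col] / vehicle.mean()
    return out


def _four_pl(log10_dose: np.ndarray, top: float, bottom: float,
             log10_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_dose - log10_ic50) * hill))


def fit_dose_response(
    log10_dose: np.ndarray,
    viability: np.ndarray,
    sample: str = "",
    drug: str = "",
    robust: bool = True,
) -> DoseResponseFit:
    """Fit the four-parameter log-logistic model to (log10 dose, viability) pairs.

    ``robust=True`` uses the soft-L1 loss (an M-estimator close in spirit to
    GraphPad's robust regression); otherwise plain least squares.  Several
    starting points (hill slopes and IC50 anchors across the dose range) are
    tried and the best final cost wins.  A fit whose response span is
    negligible or whose IC50 falls far outside the tested range is flagged
    unconstrained: ``converged=False`` and IC50 reported as NaN.
    """
    x = np.asarray(log10_dose, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log10_dose and viability must be equal-length 1-D arrays")
    n_distinct = len(np.unique(x))
    if n_distinct < 4:
        raise ValueError(f"need >= 4 distinct positive doses, got {n_distinct}")

    lo, hi = x.min(), x.max()
    y_top0 = float(np.percentile(y, 95))
    y_bot0 = float(np.percentile(y, 5))
    bounds = (
        np.array([-50.0, -50.0, lo - 3.0, 0.05]),
        np.array([250.0, 250.0, hi + 3.0, 10.0]),
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _four_pl(x, *theta) - y

    best = None
    loss = "soft_l1" if robust else "linear"
    for ic50_0 in np.linspace(lo, hi, 4):
        for hill_0 in (0.5, 1.0, 2.0):
            theta0 = np.clip(
                np.array([max(y_top0, y_bot0 + 1.0), y_bot0, ic50_0, hill_0]),
                bounds[0], bounds[1],
            )
            try:
                res = optimize.least_squares(
                    residuals, theta0, bounds=bounds, loss=loss, f_scale=5.0,
                    max_nfev=2000,
                )
            except Exception:  # numerical failure at one start is not fatal
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return DoseResponseFit(sample, drug, math.nan, math.nan, math.nan,
                               math.nan, math.nan, math.nan, False, math.nan)

    top, bottom, l_ic50, hill = best.x
    if bottom > top:  # model is symmetric under (top<->bottom, hill->-hill)
        top, bottom, hill = bottom, top, -hill
    span = top - bottom
    in_range = (lo - 1.5) <= l_ic50 <= (hi + 1.5)
    constrained = bool(best.success) and span > 1.0 and in_range
    resid = _four_pl(x, top, bottom, l_ic50, hill) - y
    rms = float(np.sqrt(np.mean(resid ** 2)))
    auc = compute_auc(x, y)
    if not constrained:
        return DoseResponseFit(sample, drug, float(top), float(bottom), math.nan,
                               float(hill), math.nan, auc, False, rms)
    return DoseResponseFit(
        sample, drug, float(top), float(bottom), float(l_ic50), float(hill),
        float(10.0 ** l_ic50), auc, True, rms,
    )


def compute_auc(log10_dose: np.ndarray, viability: np.ndarray) -> float:
    """Total AUC: trapezoidal area of mean viability vs log10 dose.

    Replicate viabilities at the same dose are averaged first, negative
    means floored at 0, and the trapezoid taken over the observed positive-
    dose range (units: percent x log10-µM).  Vehicle (dose 0) points must be
    excluded by the caller; they have no place on the log axis.
    """
    x = np.asarray(log10_dose, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    grid = np.unique(x)
    if len(grid) < 2:
        raise ValueError(f"need >= 2 distinct positive doses, got {len(grid)}")
    means = np.array([y[x == g].mean() for g in grid])
    means = np.maximum(means, 0.0)
    return float(np.trapezoid(means, grid))


def fit_table(
    t: pd.DataFrame,
    robust: bool = True,
    viability_col: str = "viability_pct",
) -> pd.DataFrame:
    """Fit every (sample, drug) of a normalized viability table.

    Returns one row per (sample, drug) with the fitted parameters, IC50,
    AUC and convergence flag.  Vehicle rows (dose 0) are dropped before
    fitting — they enter only through normalization.
    """
    _check_viability_table(t, viability_col)
    rows = []
    for (sample, drug), grp in t.groupby(["sample", "drug"], sort=False):
        pos = grp[grp["dose_uM"] > 0]
        fit = fit_dose_response(
            np.log10(pos["dose_uM"].to_numpy()),
            pos[viability_col].to_numpy(),
            sample=str(sample),
            drug=str(drug),
            robust=robust,
        )
        rows.append(
            {
                "sample": fit.sample, "drug": fit.drug, "top": fit.top,
                "bottom": fit.bottom, "hill": fit.hill, "ic50_uM": fit.ic50,
                "log10_ic50": fit.log10_ic50, "auc": fit.auc,
                "converged": fit.converged, "residual_scale": fit.residual_scale,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    auc_by_sample: dict[str, float],
    labels: dict[str, str],
) -> dict:
    """Compare AUC between MYC-high and MYC-low samples.

    Returns per-group n, mean and SD, the two-sided Mann-Whitney U p-value
    (exact when sample sizes allow and no ties are present), a Welch t-test
    p-value alongside, and the direction of the difference in means.
    """
    groups: dict[str, list[float]] = {}
    for sample, auc in auc_by_sample.items():
        if sample not in labels:
            raise ValueError(f"sample {sample!r} has no label")
        groups.setdefault(labels[sample], []).append(auc)
    names = sorted(groups)
    if len(names) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {names}")
    a, b = (np.asarray(groups[n], dtype=float) for n in names)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    welch = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": {
            names[0]: {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else math.nan},
            names[1]: {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1)) if len(b) > 1 else math.nan},
        },
        "p_mannwhitney": float(mw.pvalue),
        "u_statistic": float(mw.statistic),
        "p_welch": float(welch.pvalue),
        "direction": f"{names[0]} {'<' if a.mean() < b.mean() else '>=' } {names[1]}",
    }


def cross_drug_correlation(
    auc_drug1: dict[str, float],
    auc_drug2: dict[str, float],
) -> dict:
    """Pearson correlation of per-sample AUC between two drugs.

    Computed over samples screened against both drugs; requires at least
    three shared samples.
    """
    shared = [s for s in auc_drug1 if s in auc_drug2]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    x = np.array([auc_drug1[s] for s in shared])
    y = np.array([auc_drug2[s] for s in shared])
    r, p = stats.pearsonr(x, y)
    return {"n": len(shared), "r": float(r), "p": float(p), "samples": shared}
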