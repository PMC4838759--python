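"""Distribution-coefficient estimation by regression through the origin.

The distribution coefficient K for an ordered matrix pair (y, x) is the
slope of the no-intercept least-squares fit y = K x:

    beta = sum(x*y) / sum(x^2)
    se   = sqrt( [sum((y - beta*x)^2) / (n - 1)] / sum(x^2) )

One parameter is estimated, so the residual degrees of freedom are n - 1.
Goodness of fit for the no-intercept model is the Rest^2 statistic,

    Rest^2 = 1 - SSE_no_intercept / SST_corrected,

where SST_corrected = sum((y - mean(y))^2) is the corrected total sum of
squares of the companion with-intercept model. Rest^2 is at most 1 and can
be negative for pathological fits; when the true intercept is zero it
tracks the ordinary with-intercept R^2, which is also reported.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DEFAULT_PAIRS,
    DegenerateDataError,
    DistributionFit,
    InsufficientDataError,
)
from .registry import summary_group

#: Chemicals whose below-IDL fraction exceeds this in either matrix of a
#: pair get a low-reliability flag on the fit (estimate unchanged).
LOW_RELIABILITY_CENSORING = 0.50


def fit_through_origin(x, y, chemical: str = "", y_matrix: str = "",
                       x_matrix: str = "") -> DistributionFit:
    """Fit y = beta * x through the origin; also report the with-intercept
    companion fit (slope, intercept, R^2) for comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DegenerateDataError("all x values are zero; slope is undefined")

    beta = float(np.sum(x * y)) / sxx
    sse = float(np.sum((y - beta * x) ** 2))
    se = np.sqrt(sse / (n - 1) / sxx)

    sst = float(np.sum((y - y.mean()) ** 2))
    r2_est = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else np.nan)

    # with-intercept companion
    if np.ptp(x) > 0:
        res = stats.linregress(x, y)
        slope_i, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        slope_i_se = res.stderr
    else:
        slope_i = intercept = slope_i_se = r2 = np.nan
    return DistributionFit(
        chemical=chemical,
        y_matrix=y_matrix,
        x_matrix=x_matrix,
        n=n,
        beta=beta,
        se=float(se),
        r2=None if np.isnan(r2) else float(r2),
        r2_est=float(r2_est) if not np.isnan(r2_est) else None,
        intercept_beta=None if np.isnan(slope_i) else float(slope_i),
        intercept_se=None if np.isnan(slope_i_se) else float(slope_i_se),
        intercept=None if np.isnan(intercept) else float(intercept),
    )


def fit_all_pairs(panel: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """One through-origin fit per chemical per available ordered matrix pair.

    Expects a cleaned, collapsed panel (one row per participant, chemical
    and matrix). Samples flagged not-accepted are ignored; fits use
    participants with both members of the pair. Per-chemical failures
    (too few pairs, degenerate x) are logged as skips, not fatal. Chemicals
    with more than half of either matrix's values below the IDL keep their
    estimate but carry ``low_reliability = True``.
    """
    data = panel
    if "accepted" in data.columns:
        data = data[data["accepted"]]
    available = set(data["matrix"].unique())
    rows = []
    for chemical, grp in data.groupby("chemical", sort=False):
        wide = grp.pivot_table(index="participant_id", columns="matrix",
                               values="concentration_ng_per_L", aggfunc="mean")
        censored = grp.pivot_table(index="participant_id", columns="matrix",
                                   values="below_idl", aggfunc="any")
        for y_m, x_m in pairs:
            if y_m not in available or x_m not in available:
                continue
            if y_m not in wide.columns or x_m not in wide.columns:
                continue
            sub = wide[[y_m, x_m]].dropna()
            try:
                fit = fit_through_origin(sub[x_m], sub[y_m], chemical, y_m, x_m)
            except (InsufficientDataError, DegenerateDataError):
                continue
            cens = censored.loc[sub.index]
            if (cens[y_m].mean() > LOW_RELIABILITY_CENSORING
                    or cens[x_m].mean() > LOW_RELIABILITY_CENSORING):
                fit = replace(fit, low_reliability=True)
            rows.append(fit)
    return fits_to_frame(rows)


def fits_to_frame(fits) -> pd.DataFrame:
    """Tidy DataFrame view of a sequence of :class:`DistributionFit`."""
    return pd.DataFrame(
        [
            {
                "chemical": f.chemical,
                "y_matrix": f.y_matrix,
                "x_matrix": f.x_matrix,
                "n": f.n,
                "beta": f.beta,
                "se": f.se,
                "r2": np.nan if f.r2 is None else f.r2,
                "r2_est": np.nan if f.r2_est is None else f.r2_est,
                "intercept_beta": np.nan if f.intercept_beta is None else f.intercept_beta,
                "intercept": np.nan if f.intercept is None else f.intercept,
                "low_reliability": f.low_reliability,
            }
            for f in fits
        ],
        columns=["chemical", "y_matrix", "x_matrix", "n", "beta", "se", "r2",
                 "r2_est", "intercept_beta", "intercept", "low_reliability"],
    )


def summarize_by_class(fits: pd.DataFrame, chemicals: pd.DataFrame) -> pd.DataFrame:
    """Class summaries of fitted coefficients per matrix pair.

    Groups are pesticides/CHCs, PCBs, PBDE congeners, and
    tetrabromobisphenol A as its own single-member group. Reports the
    arithmetic mean, sample SD (n - 1 denominator; 0 with a degeneracy
    flag for single-member groups), min, max and member count, over
    chemicals with a reported fit only.
    """
    classes = chemicals.set_index("chemical")["chem_class"]
    fits = fits.dropna(subset=["beta"]).copy()
    fits["group"] = [
        summary_group(c, classes.get(c, "pcb")) for c in fits["chemical"]
    ]
    rows = []
    for (group, y_m, x_m), grp in fits.groupby(["group", "y_matrix", "x_matrix"]):
        betas = grp["beta"].to_numpy()
        rows.append(
            {
                "chem_class": group,
                "y_matrix": y_m,
                "x_matrix": x_m,
                "n_chemicals": len(betas),
                "mean_beta": betas.mean(),
                "sd_beta": betas.std(ddof=1) if len(betas) > 1 else 0.0,
                "min_beta": betas.min(),
                "max_beta": betas.max(),
                "degenerate_sd": len(betas) < 2,
            }
        )
    return pd.DataFrame(rows)


def dbs_agreement(fits: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Agreement of whole blood and DBS: coefficient range and per-chemical
    two-sided t-tests of H0: beta = 1 using (beta - 1)/se with n - 1 df.

    Returns the min/max coefficient, a per-chemical table with t statistics
    and p-values, and the fraction of chemicals whose coefficient does not
    differ from one at level ``alpha``.
    """
    wd = fits[(fits["y_matrix"] == "whole_blood") & (fits["x_matrix"] == "dbs")]
    rows = []
    for _, row in wd.iterrows():
        if row["se"] > 0:
            t = (row["beta"] - 1.0) / row["se"]
            p = 2.0 * stats.t.sf(abs(t), df=int(row["n"]) - 1)
        else:
            # zero SE: any deviation from one is formally significant
            t = np.inf if row["beta"] != 1.0 else 0.0
            p = 0.0 if row["beta"] != 1.0 else 1.0
        rows.append(
            {"chemical": row["chemical"], "beta": row["beta"], "se": row["se"],
             "n": int(row["n"]), "t": t, "p_value": p,
             "consistent_with_unity": p >= alpha}
        )
    table = pd.DataFrame(rows)
    return {
        "min_beta": float(table["beta"].min()) if len(table) else np.nan,
        "max_beta": float(table["beta"].max()) if len(table) else np.nan,
        "fraction_unity": float(table["consistent_with_unity"].mean()) if len(table) else np.nan,
        "per_chemical": table,
    }
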