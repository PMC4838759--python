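"""Effects of demographics and smoking on plasma/whole-blood ratios.

Each retained chemical gets one multivariable ordinary-least-squares model
of the per-participant concentration ratio on age (continuous, per year)
and four binary indicators — sex (reference female), race (reference
white), education (reference graduate degree or above) and smoking status
(reference never-smoker) — fitted jointly, so with an intercept the
residual degrees of freedom are n - 6. Ratios are modelled on the natural
scale, matching how the effect sizes are reported.

These are exploratory screens: with four or five terms tested per chemical
at alpha = 0.05 the family-wise false-rejection probability is
1 - (1 - alpha)^m (about 19% for m = 4), computed by
:func:`familywise_error`; no adjustment is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import InsufficientDataError, ValidationError

log = logging.getLogger("popblood")

#: Design terms in reporting order: (term, builder).
TERMS = [
    ("age", lambda p: p["age_years"].astype(float)),
    ("sex_male", lambda p: (p["sex"] == "male").astype(float)),
    ("race_other", lambda p: (p["race"] == "other").astype(float)),
    ("education_below_masters", lambda p: (p["education"] == "below_masters").astype(float)),
    ("smoking_former_or_current", lambda p: (p["smoking"] == "former_or_current").astype(float)),
]


@dataclass
class CovariateEffects:
    """Fitted covariate model for one chemical."""

    chemical: str
    terms: pd.DataFrame  # term, estimate, se, p_value, estimable
    n: int
    residual_sd: float


def ratio_table(panel: pd.DataFrame, y_matrix: str = "plasma",
                x_matrix: str = "whole_blood") -> pd.DataFrame:
    """Per-participant concentration ratios from a cleaned, collapsed panel.

    Rows where either member is a half-IDL substitute are flagged
    ``substituted`` (kept by default; the flag lets callers drop them).
    Zero denominators are dropped with a logged warning.
    """
    wide = panel.pivot_table(index=["chemical", "participant_id"], columns="matrix",
                             values="concentration_ng_per_L", aggfunc="mean")
    flags = panel.pivot_table(index=["chemical", "participant_id"], columns="matrix",
                              values="below_idl", aggfunc="any")
    rows = []
    for idx in wide.index:
        y = wide.loc[idx].get(y_matrix)
        x = wide.loc[idx].get(x_matrix)
        if pd.isna(y) or pd.isna(x):
            continue
        if x == 0:
            log.warning("ratio_table: zero %s value for %s, dropped", x_matrix, idx)
            continue
        rows.append(
            {
                "chemical": idx[0],
                "participant_id": idx[1],
                "ratio": y / x,
                "substituted": bool(flags.loc[idx].get(y_matrix, False)
                                    or flags.loc[idx].get(x_matrix, False)),
            }
        )
    return pd.DataFrame(rows, columns=["chemical", "participant_id", "ratio", "substituted"])


def fit_covariate_model(ratios: pd.DataFrame, participants: pd.DataFrame,
                        chemical: str = "") -> CovariateEffects:
    """OLS of the ratio on age and the four binary indicators jointly.

    ``ratios`` needs ``participant_id`` and ``ratio`` columns (pre-filtered
    to one chemical). Constant or collinear covariates are dropped and
    reported as inestimable rather than failing the whole model. Requires
    at least 8 complete rows.
    """
    data = ratios.merge(participants, on="participant_id", how="inner").dropna(
        subset=["ratio", "age_years", "sex", "race", "education", "smoking"]
    )
    n = len(data)
    if n < 8:
        raise InsufficientDataError(
            f"{chemical or 'ratio model'}: {n} complete rows < 8"
        )
    y = data["ratio"].to_numpy(dtype=float)
    columns, names, inestimable = [np.ones(n)], ["intercept"], []
    for term, build in TERMS:
        col = build(data).to_numpy()
        candidate = np.column_stack(columns + [col])
        if np.ptp(col) == 0 or np.linalg.matrix_rank(candidate) <= len(columns):
            inestimable.append(term)
            continue
        columns.append(col)
        names.append(term)
    X = np.column_stack(columns)
    fit = sm.OLS(y, X).fit()

    rows = []
    for term, _ in TERMS:
        if term in names:
            j = names.index(term)
            rows.append({"term": term, "estimate": fit.params[j], "se": fit.bse[j],
                         "p_value": fit.pvalues[j], "estimable": True})
        else:
            rows.append({"term": term, "estimate": np.nan, "se": np.nan,
                         "p_value": np.nan, "estimable": False})
    terms = pd.DataFrame(rows)
    resid_sd = float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0
    return CovariateEffects(chemical=chemical, terms=terms, n=n, residual_sd=resid_sd)


def fit_all_covariate_models(ratios: pd.DataFrame,
                             participants: pd.DataFrame) -> pd.DataFrame:
    """One covariate model per chemical; returns a tidy long table with
    significance marks at p < 0.05 and p < 0.01."""
    rows = []
    for chemical, grp in ratios.groupby("chemical", sort=False):
        try:
            eff = fit_covariate_model(grp, participants, chemical)
        except InsufficientDataError as err:
            log.warning("covariates: %s", err)
            continue
        for _, t in eff.terms.iterrows():
            p = t["p_value"]
            rows.append(
                {
                    "chemical": chemical,
                    "term": t["term"],
                    "estimate": t["estimate"],
                    "se": t["se"],
                    "p_value": p,
                    "estimable": t["estimable"],
                    "significance": ("**" if p < 0.01 else "*" if p < 0.05 else "")
                    if pd.notna(p) else "",
                    "n": eff.n,
                    "residual_sd": eff.residual_sd,
                }
            )
    return pd.DataFrame(rows)


def familywise_error(alpha: float, m: int) -> float:
    """Probability of at least one false rejection over m independent
    tests at level alpha: 1 - (1 - alpha)^m."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** m
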