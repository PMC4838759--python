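"""Concentration conversion between plasma, whole blood and DBS.

Conversions multiply or divide by the ordered-pair distribution
coefficient; a direct pair coefficient is preferred, and otherwise the
path pivots through whole blood (the canonical, most precisely measured
matrix). Coefficient uncertainty propagates first-order on the relative
scale: a single-coefficient path carries se/beta, a pivoted path the
root-sum-square of its legs.

Fallback policy follows the experimental recommendations: a PCB or PBDE
congener missing from the coefficient table may use the class-average
plasma/whole-blood coefficient, while pesticides/CHCs and
tetrabromobisphenol A require compound-specific values (class averaging
must be forced explicitly). Whole-blood/DBS coefficients statistically
consistent with one default to exactly 1 (flagged ``unity_dbs``),
overridable with ``prefer_fitted=True``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MATRICES,
    ConversionResult,
    PolicyError,
    SchemaError,
    TargetLookupError,
)
from .registry import builtin_chemicals, builtin_coefficients, summary_group

log = logging.getLogger("popblood")

UNITY_ALPHA = 0.05


def class_average_coefficients(coefficients: pd.DataFrame | None = None,
                               chemicals: pd.DataFrame | None = None) -> dict:
    """Average plasma/whole-blood coefficient per reporting group.

    Returns ``{group: (mean_beta, relative_sd)}`` where the relative SD of
    the group's betas serves as the fallback's relative uncertainty.
    """
    table = builtin_coefficients() if coefficients is None else coefficients
    reg = (builtin_chemicals() if chemicals is None else chemicals).set_index("chemical")
    pw = table[(table["y_matrix"] == "plasma") & (table["x_matrix"] == "whole_blood")]
    out = {}
    groups = {}
    for _, row in pw.iterrows():
        if row["chemical"] not in reg.index:
            continue
        group = summary_group(row["chemical"], reg.loc[row["chemical"], "chem_class"])
        groups.setdefault(group, []).append(float(row["beta"]))
    for group, betas in groups.items():
        mean = float(np.mean(betas))
        sd = float(np.std(betas, ddof=1)) if len(betas) > 1 else 0.0
        out[group] = (mean, sd / mean if mean else 0.0)
    return out


def _pair_row(table, chemical, y_m, x_m):
    hit = table[(table["chemical"] == chemical) & (table["y_matrix"] == y_m)
                & (table["x_matrix"] == x_m)]
    return None if hit.empty else hit.iloc[0]


def _unity_consistent(row, alpha=UNITY_ALPHA) -> bool:
    se = float(row["se"])
    if se <= 0:
        return float(row["beta"]) == 1.0
    t = (float(row["beta"]) - 1.0) / se
    n = int(row["n"]) if "n" in row and pd.notna(row["n"]) else 21
    return 2.0 * stats.t.sf(abs(t), df=n - 1) >= alpha


def _leg(table, chemical, from_matrix, to_matrix, prefer_fitted):
    """Single-coefficient step, or None. Returns (factor, rel_se, source)."""
    row = _pair_row(table, chemical, to_matrix, from_matrix)
    invert = False
    if row is None:
        row = _pair_row(table, chemical, from_matrix, to_matrix)
        invert = True
    if row is None:
        return None
    beta, se = float(row["beta"]), float(row["se"])
    rel_se = se / beta
    source = "bundled_table"
    if {from_matrix, to_matrix} == {"whole_blood", "dbs"} and not prefer_fitted \
            and _unity_consistent(row):
        return 1.0, rel_se, "unity_dbs"
    return (1.0 / beta if invert else beta), rel_se, source


def resolve_coefficient(chemical: str, from_matrix: str, to_matrix: str,
                        coefficients: pd.DataFrame | None = None,
                        chemicals: pd.DataFrame | None = None,
                        force_class_average: bool = False,
                        prefer_fitted: bool = False):
    """Multiplicative factor taking ``from_matrix`` concentrations to
    ``to_matrix``, with its relative SE and provenance label."""
    for m in (from_matrix, to_matrix):
        if m not in MATRICES:
            raise SchemaError(f"unknown matrix {m!r}")
    if from_matrix == to_matrix:
        return 1.0, 0.0, "identity"
    table = builtin_coefficients() if coefficients is None else coefficients
    source_tag = "bundled_table" if coefficients is None else "fitted"

    direct = _leg(table, chemical, from_matrix, to_matrix, prefer_fitted)
    if direct is not None:
        factor, rel_se, source = direct
        return factor, rel_se, source if source == "unity_dbs" else source_tag

    # pivot through whole blood
    if "whole_blood" not in (from_matrix, to_matrix):
        leg1 = _leg(table, chemical, from_matrix, "whole_blood", prefer_fitted)
        leg2 = _leg(table, chemical, "whole_blood", to_matrix, prefer_fitted)
        if leg1 is not None and leg2 is not None:
            factor = leg1[0] * leg2[0]
            rel_se = math.hypot(leg1[1], leg2[1])
            return factor, rel_se, f"{source_tag}_pivot"

    # class-average fallback, plasma <-> whole blood only
    if {from_matrix, to_matrix} == {"plasma", "whole_blood"}:
        reg = (builtin_chemicals() if chemicals is None else chemicals).set_index("chemical")
        if chemical not in reg.index:
            raise TargetLookupError(
                f"unknown chemical {chemical!r}: no coefficient and no class"
            )
        group = summary_group(chemical, reg.loc[chemical, "chem_class"])
        averages = class_average_coefficients(table, chemicals)
        if group not in averages:
            raise TargetLookupError(f"no class average available for group {group!r}")
        if group not in ("pcb", "pbde") and not force_class_average:
            raise PolicyError(
                f"{chemical} ({group}): compound-specific coefficients are "
                "required for pesticides/CHCs and TBBPa; pass "
                "force_class_average=True to override"
            )
        beta, rel_se = averages[group]
        factor = beta if to_matrix == "plasma" else 1.0 / beta
        return factor, rel_se, "class_average"

    raise TargetLookupError(
        f"no conversion path for {chemical} {from_matrix} -> {to_matrix}"
    )


def convert(concentration: float, chemical: str, from_matrix: str, to_matrix: str,
            coefficients: pd.DataFrame | None = None,
            chemicals: pd.DataFrame | None = None,
            force_class_average: bool = False,
            prefer_fitted: bool = False) -> ConversionResult:
    """Convert one concentration (ng/L) between matrices."""
    factor, rel_se, source = resolve_coefficient(
        chemical, from_matrix, to_matrix, coefficients, chemicals,
        force_class_average, prefer_fitted,
    )
    return ConversionResult(
        chemical=chemical,
        from_matrix=from_matrix,
        to_matrix=to_matrix,
        input_concentration=float(concentration),
        converted_concentration=float(concentration) * factor,
        relative_se=rel_se,
        source=source,
    )


def batch_convert(panel: pd.DataFrame, target_matrix: str,
                  coefficients: pd.DataFrame | None = None,
                  chemicals: pd.DataFrame | None = None,
                  force_class_average: bool = False,
                  prefer_fitted: bool = False) -> pd.DataFrame:
    """Re-express a collapsed panel in ``target_matrix``.

    Rows without a conversion path pass through unchanged with
    ``converted = False``; provenance and relative-SE columns are appended.
    Half-IDL substitutes convert like any other value but keep their
    ``below_idl`` flag so users can judge them separately.
    """
    out = panel.copy()
    factors, rel_ses, sources, ok = [], [], [], []
    cache = {}
    for _, row in out.iterrows():
        key = (row["chemical"], row["matrix"])
        if key not in cache:
            try:
                cache[key] = resolve_coefficient(
                    row["chemical"], row["matrix"], target_matrix,
                    coefficients, chemicals, force_class_average, prefer_fitted,
                )
            except (TargetLookupError, PolicyError) as err:
                log.warning("batch_convert: %s", err)
                cache[key] = None
        hit = cache[key]
        if hit is None:
            factors.append(1.0), rel_ses.append(np.nan), sources.append("unconvertible")
            ok.append(False)
        else:
            factors.append(hit[0]), rel_ses.append(hit[1]), sources.append(hit[2])
            ok.append(True)
    out["concentration_ng_per_L"] = out["concentration_ng_per_L"] * np.asarray(factors)
    out.loc[ok, "matrix"] = target_matrix
    out["converted"] = ok
    out["conversion_source"] = sources
    out["conversion_relative_se"] = rel_ses
    return out
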