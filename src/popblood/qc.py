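"""Data cleaning: replicate acceptance and averaging, half-IDL substitution
for censored values, detection-frequency exclusion, normality and
correlation summaries, and a modified Bland-Altman outlier screen.

The pipeline order is fixed — replicate averaging, then censoring
substitution, then the detection filter, then the outlier screen — and is
idempotent on its own output. Outlier handling is report-and-flag only:
points are never deleted without an explicit caller directive, preserving
an audit trail.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError
from .io import idl_lookup

#: Replicate groups whose relative range (max - min) / mean reaches this
#: value are flagged not-accepted ("varied by less than 10%" acceptance).
REPLICATE_RANGE_LIMIT = 0.10

#: Chemicals detected in fewer than this fraction of samples (per matrix)
#: are excluded from that matrix's analyses. Exactly at the boundary is kept.
DETECTION_THRESHOLD = 0.25

GROUP_KEYS = ["participant_id", "chemical", "matrix"]


@dataclass
class CleaningReport:
    """Accumulated QC output; individual stages fill their own slot."""

    replicates: Optional[pd.DataFrame] = None   # per-group relative range / accepted
    detection: Optional[pd.DataFrame] = None    # per chemical x matrix frequency
    substituted_count: Optional[int] = None
    outliers: Optional[pd.DataFrame] = None     # Bland-Altman flags
    ba_slopes: Optional[pd.DataFrame] = None    # log-ratio-vs-level slopes
    notes: list = field(default_factory=list)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        for slot in ("replicates", "detection", "substituted_count", "outliers", "ba_slopes"):
            val = getattr(other, slot)
            if val is not None:
                setattr(self, slot, val)
        self.notes.extend(other.notes)
        return self


def average_replicates(panel: pd.DataFrame):
    """Collapse replicate groups to their arithmetic mean.

    Groups whose relative range (max - min) / mean is >= 10% are flagged
    ``accepted = False`` (and excluded from downstream fits); all-zero
    groups have no defined relative range and are flagged degenerate. A
    collapsed sample keeps ``below_idl = True`` only when every replicate
    was below the IDL.
    """
    g = panel.groupby(GROUP_KEYS, sort=False)["concentration_ng_per_L"]
    out = g.mean().reset_index()
    spread = (g.max() - g.min()).reset_index(drop=True)
    n_rep = g.size().reset_index(drop=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_range = np.where(out["concentration_ng_per_L"] > 0,
                             spread / out["concentration_ng_per_L"], np.nan)
    degenerate = (out["concentration_ng_per_L"] == 0) & (n_rep > 1)
    accepted = (~degenerate) & ((n_rep == 1) | (rel_range < REPLICATE_RANGE_LIMIT))
    # re-running on an already-collapsed panel must be a no-op: carry
    # earlier acceptance decisions and replicate counts through
    if "accepted" in panel.columns:
        prior = panel.groupby(GROUP_KEYS, sort=False)["accepted"].all().reset_index(drop=True)
        accepted = accepted & prior
    if "n_replicates" in panel.columns:
        n_rep = panel.groupby(GROUP_KEYS, sort=False)["n_replicates"].sum().reset_index(drop=True)

    flags = panel.groupby(GROUP_KEYS, sort=False)["below_idl"].all().reset_index(drop=True)
    out["replicate"] = 1
    out["below_idl"] = flags
    out["n_replicates"] = n_rep
    out["accepted"] = accepted
    report = out[GROUP_KEYS].copy()
    report["replicate_relative_range"] = rel_range
    report["accepted"] = accepted
    report["degenerate"] = degenerate
    cols = GROUP_KEYS + ["replicate", "concentration_ng_per_L", "below_idl",
                         "n_replicates", "accepted"]
    return out[cols], CleaningReport(replicates=report)


def censor_substitute(panel: pd.DataFrame, chemicals) -> pd.DataFrame:
    """Replace below-IDL measurements by half the matrix IDL.

    ``chemicals`` is either a chemicals-table DataFrame or a mapping
    ``(chemical, matrix) -> IDL``. A below-IDL row whose chemical/matrix has
    no IDL raises :class:`ConfigurationError`.
    """
    idls = chemicals if isinstance(chemicals, dict) else idl_lookup(chemicals)
    panel = panel.copy()
    below = panel["below_idl"]
    if not below.any():
        return panel
    substituted = []
    for idx in panel.index[below]:
        key = (panel.at[idx, "chemical"], panel.at[idx, "matrix"])
        if key not in idls:
            raise ConfigurationError(
                f"no IDL configured for chemical {key[0]!r} in matrix {key[1]!r}"
            )
        substituted.append(idls[key] / 2.0)
    panel.loc[below, "concentration_ng_per_L"] = substituted
    return panel


def detection_filter(panel: pd.DataFrame, threshold: float = DETECTION_THRESHOLD):
    """Drop chemicals detected in fewer than ``threshold`` of a matrix's
    samples from that matrix's analyses.

    The boundary is kept: a detection frequency exactly equal to the
    threshold is retained. Returns the filtered panel and a report listing
    per chemical x matrix frequencies.
    """
    freq = (
        panel.groupby(["chemical", "matrix"], sort=False)["below_idl"]
        .agg(lambda s: 1.0 - s.mean())
        .rename("detection_frequency")
        .reset_index()
    )
    freq["excluded"] = freq["detection_frequency"] < threshold
    keep = freq[~freq["excluded"]][["chemical", "matrix"]]
    filtered = panel.merge(keep, on=["chemical", "matrix"], how="inner")
    return filtered, CleaningReport(detection=freq)


def bland_altman_screen(panel: pd.DataFrame, pair=("plasma", "whole_blood"),
                        z_threshold: float = 3.0) -> CleaningReport:
    """Modified Bland-Altman screen on a collapsed panel.

    For each chemical with both matrices, the per-participant log-ratio
    log(y/x) is compared with the chemical's mean log-ratio; participants
    deviating by more than ``z_threshold`` sample SDs are flagged. The
    slope of the log-ratio on the mean level (y + x)/2 supports the
    "coefficient does not vary by concentration" check. Chemicals with
    fewer than 3 complete pairs are skipped with a warning.
    """
    y_m, x_m = pair
    wide = (
        panel[panel["matrix"].isin(pair)]
        .pivot_table(index=["chemical", "participant_id"], columns="matrix",
                     values="concentration_ng_per_L", aggfunc="mean")
        .reset_index()
    )
    flags, slopes = [], []
    for chemical, grp in wide.groupby("chemical", sort=False):
        grp = grp.dropna(subset=[y_m, x_m])
        grp = grp[(grp[y_m] > 0) & (grp[x_m] > 0)]
        if len(grp) < 3:
            warnings.warn(
                f"Bland-Altman screen: {chemical} skipped "
                f"({len(grp)} complete pairs < 3)"
            )
            continue
        logr = np.log(grp[y_m].to_numpy() / grp[x_m].to_numpy())
        level = (grp[y_m].to_numpy() + grp[x_m].to_numpy()) / 2.0
        mu, sd = logr.mean(), logr.std(ddof=1)
        z = np.zeros_like(logr) if sd == 0 else (logr - mu) / sd
        slope = np.nan
        if np.ptp(level) > 0:
            slope = stats.linregress(level, logr).slope
        slopes.append(
            {"chemical": chemical, "pair": f"{y_m}/{x_m}", "n": len(grp),
             "mean_log_ratio": mu, "sd_log_ratio": sd, "level_slope": slope}
        )
        for pid, zi, ri in zip(grp["participant_id"], z, logr):
            if abs(zi) > z_threshold:
                flags.append(
                    {"chemical": chemical, "participant_id": pid,
                     "pair": f"{y_m}/{x_m}", "log_ratio": ri, "z": zi}
                )
    return CleaningReport(
        outliers=pd.DataFrame(flags, columns=["chemical", "participant_id",
                                              "pair", "log_ratio", "z"]),
        ba_slopes=pd.DataFrame(slopes),
    )


@functools.lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_mc: int = 10000) -> np.ndarray:
    """Monte-Carlo null distribution of the KS statistic with estimated
    mean/SD (Lilliefors-style), cached per sample size. Internally seeded
    so p-values are reproducible."""
    rng = np.random.default_rng(20160421)
    samples = rng.standard_normal((n_mc, n))
    return np.sort(_ks_stat_rows(samples))


def _ks_stat_rows(samples: np.ndarray) -> np.ndarray:
    n = samples.shape[1]
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((samples - mu) / sd, axis=1)
    cdf = stats.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = (grid_hi - cdf).max(axis=1)
    d_minus = (cdf - grid_lo).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_pvalue(x, n_mc: int = 10000) -> float:
    """Normality p-value: KS distance with estimated parameters, referred
    to a Monte-Carlo null of ``n_mc`` normal samples of the same size."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 4 or np.ptp(x) == 0:
        return np.nan
    stat = _ks_stat_rows(x[None, :])[0]
    null = _lilliefors_null(len(x), n_mc)
    return float((np.sum(null >= stat) + 1) / (len(null) + 1))


def panel_summaries(panel: pd.DataFrame):
    """Descriptive statistics and between-chemical correlations.

    Returns ``(summary, correlations)``: per chemical x matrix mean, SD,
    min, median, max, and Monte-Carlo Lilliefors normality p-value; and per
    matrix the Spearman rank correlation (product-moment correlation of
    mid-ranks) for every chemical pair. Constant vectors yield missing
    correlations.
    """
    rows = []
    for (chemical, matrix), grp in panel.groupby(["chemical", "matrix"], sort=False):
        x = grp["concentration_ng_per_L"].to_numpy()
        rows.append(
            {
                "chemical": chemical,
                "matrix": matrix,
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else np.nan,
                "min": x.min(),
                "median": np.median(x),
                "max": x.max(),
                "ks_normality_p": lilliefors_pvalue(x),
            }
        )
    summary = pd.DataFrame(rows)

    corr_rows = []
    for matrix, grp in panel.groupby("matrix", sort=False):
        wide = grp.pivot_table(index="participant_id", columns="chemical",
                               values="concentration_ng_per_L", aggfunc="mean")
        if wide.shape[1] < 2:
            continue
        corr = wide.corr(method="spearman", min_periods=3)
        chems = list(corr.columns)
        for i, a in enumerate(chems):
            for b in chems[i + 1:]:
                r = corr.loc[a, b]
                if wide[a].nunique() <= 1 or wide[b].nunique() <= 1:
                    r = np.nan  # constant vector: rank correlation undefined
                corr_rows.append({"matrix": matrix, "chemical_a": a,
                                  "chemical_b": b, "spearman_r": r})
    correlations = pd.DataFrame(
        corr_rows, columns=["matrix", "chemical_a", "chemical_b", "spearman_r"]
    )
    return summary, correlations


def clean_pipeline(panel: pd.DataFrame, chemicals,
                   detection_threshold: float = DETECTION_THRESHOLD,
                   ba_pair=("plasma", "whole_blood"), ba_z: float = 3.0,
                   screen: bool = True):
    """Run the full cleaning pipeline in its fixed order.

    Replicate averaging -> half-IDL substitution -> detection filter ->
    Bland-Altman screen (report-only). Returns the cleaned panel and the
    combined :class:`CleaningReport`; the substituted count refers to
    below-IDL measurements among retained chemicals.
    """
    collapsed, report = average_replicates(panel)
    substituted = censor_substitute(collapsed, chemicals)
    filtered, det_report = detection_filter(substituted, detection_threshold)
    report.merge(det_report)
    report.substituted_count = int(filtered["below_idl"].sum())
    if screen:
        matrices = set(filtered["matrix"].unique())
        if set(ba_pair) <= matrices:
            report.merge(bland_altman_screen(filtered, ba_pair, ba_z))
    return filtered, report


def write_report(report: CleaningReport, path) -> None:
    """Serialize the cleaning report as a single long CSV."""
    parts = []
    for slot in ("replicates", "detection", "outliers", "ba_slopes"):
        df = getattr(report, slot)
        if df is not None and len(df):
            part = df.copy()
            part.insert(0, "section", slot)
            parts.append(part)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame({"section": []})
    if report.substituted_count is not None:
        out.attrs["substituted_count"] = report.substituted_count
    out.to_csv(path, index=False)
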