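"""Physically-based tissue/blood partition model and mass-balance bounds.

A compartment is summarized by its neutral-lipid (N), phospholipid (P) and
water (W) mass fractions. A chemical contributes its n-octanol solubility
S_o = S_w * K_ow and water solubility S_w. The partition coefficient of a
top compartment t over a bottom compartment b is

    K = (S_o*N_t + 0.7*S_w*P_t + 0.3*S_o*P_t + S_w*W_t)
        / (S_o*N_b + 0.7*S_w*P_b + 0.3*S_o*P_b + S_w*W_b)

Phospholipid behaves as a fixed 70% water-like / 30% octanol-like blend;
the split is deliberately not configurable. K depends on the solubilities
only through K_ow, satisfies K(t,b) * K(b,t) = 1, and converges for
K_ow -> inf to the lipophilic limit (N_t + 0.3*P_t) / (N_b + 0.3*P_b),
independent of water content. For the highly lipophilic pollutants handled
here (K_ow of 2e4 and up) plasma/whole-blood predictions sit essentially at
that limit, near one — well below the experimental coefficients of 1.6-2.3,
which is precisely the model's documented shortfall: it carries no protein
binding or cellular-matrix terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CompartmentComposition,
    DegenerateDataError,
    MassBalanceParams,
    ValidationError,
)


@dataclass(frozen=True)
class SolubilityPair:
    """Water solubility (mg/L) and K_ow; octanol solubility is derived."""

    s_w: float
    k_ow: float

    def __post_init__(self):
        if not (self.s_w > 0 and self.k_ow > 0):
            raise ValidationError("s_w and k_ow must be positive")

    @property
    def s_o(self) -> float:
        return self.s_w * self.k_ow

    @classmethod
    def from_log10_kow(cls, log10_kow: float, s_w: float) -> "SolubilityPair":
        return cls(s_w=s_w, k_ow=10.0 ** log10_kow)


def _mixture_solubility(sol: SolubilityPair, comp: CompartmentComposition) -> float:
    return (
        sol.s_o * comp.neutral_lipid
        + sol.s_w * 0.7 * comp.phospholipid
        + sol.s_o * 0.3 * comp.phospholipid
        + sol.s_w * comp.water
    )


def partition_coefficient(sol: SolubilityPair, top: CompartmentComposition,
                          bottom: CompartmentComposition) -> float:
    """Partition coefficient of ``top`` over ``bottom`` for one chemical."""
    denom = _mixture_solubility(sol, bottom)
    if denom == 0.0:
        raise DegenerateDataError(
            f"compartment {bottom.name!r} has zero capacity for this chemical"
        )
    return _mixture_solubility(sol, top) / denom


def lipophilic_limit(top: CompartmentComposition,
                     bottom: CompartmentComposition) -> float:
    """K_ow -> inf limit of the partition coefficient:
    (N_t + 0.3 P_t) / (N_b + 0.3 P_b), independent of water fractions."""
    denom = bottom.neutral_lipid + 0.3 * bottom.phospholipid
    if denom == 0.0:
        raise DegenerateDataError(
            f"compartment {bottom.name!r} has no lipid capacity"
        )
    return (top.neutral_lipid + 0.3 * top.phospholipid) / denom


def max_plasma_ratio(mb: MassBalanceParams = MassBalanceParams()) -> float:
    """Upper bound on the plasma/whole-blood concentration ratio, 1/w_p.

    If all analyte mass resides in the plasma fraction (weight fraction
    w_p of whole blood) and none in the cellular pellet, plasma is more
    concentrated than whole blood by exactly 1/w_p — about 1.8 at the
    default w_p = 0.55.
    """
    return 1.0 / mb.plasma_weight_fraction


def implied_plasma_mass_fraction(k_pb: float, effective_wp: float = 0.45) -> float:
    """Fraction of whole-blood analyte mass attributable to plasma,
    min(1, k_pb * effective_wp).

    ``effective_wp`` is the plasma content effectively involved in
    partitioning; 0.45 (down from the anatomical 0.55) reconciles the
    bound with the experimental coefficients.
    """
    if not k_pb > 0:
        raise ValidationError("k_pb must be > 0")
    if not 0.0 < effective_wp < 1.0:
        raise ValidationError("effective_wp must lie in (0, 1)")
    return min(1.0, k_pb * effective_wp)


def theoretical_vs_experimental(chemicals: pd.DataFrame, fits: pd.DataFrame,
                                plasma_comp: CompartmentComposition,
                                blood_comp: CompartmentComposition) -> pd.DataFrame:
    """Per-chemical model prediction vs experimental coefficient.

    ``chemicals`` must carry ``log10_kow`` and ``water_solubility_mg_per_L``;
    chemicals missing either are skipped with a note. ``fits`` supplies the
    experimental plasma~whole_blood coefficients. The returned frame also
    exposes the across-chemical prediction spread (max - min) and an
    under-prediction flag (experimental coefficient more than 1.5x the
    prediction) via ``DataFrame.attrs``.
    """
    pw = fits[(fits["y_matrix"] == "plasma") & (fits["x_matrix"] == "whole_blood")]
    pw = pw.set_index("chemical")
    rows, skipped = [], []
    for _, row in chemicals.iterrows():
        name = row["chemical"]
        if pd.isna(row.get("log10_kow")) or pd.isna(row.get("water_solubility_mg_per_L")):
            skipped.append(name)
            continue
        sol = SolubilityPair.from_log10_kow(
            float(row["log10_kow"]), float(row["water_solubility_mg_per_L"])
        )
        pred = partition_coefficient(sol, plasma_comp, blood_comp)
        beta = float(pw.loc[name, "beta"]) if name in pw.index else np.nan
        rows.append(
            {
                "chemical": name,
                "log10_kow": float(row["log10_kow"]),
                "predicted_k": pred,
                "experimental_beta": beta,
                "ratio_experimental_to_predicted": beta / pred if np.isfinite(beta) else np.nan,
                "under_predicted": bool(np.isfinite(beta) and beta / pred > 1.5),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table.attrs["prediction_spread"] = float(
            table["predicted_k"].max() - table["predicted_k"].min()
        )
    table.attrs["skipped"] = skipped
    return table
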