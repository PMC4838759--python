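"""Bundled registries: experimental distribution coefficients, chemical
metadata, and compartment compositions.

The distribution-coefficient table holds the experimentally determined
through-origin coefficients (with SEs and with-intercept R-squared) for the
three matrix pairs plasma~whole_blood (K_p/b), plasma~dbs (K_p/d) and
whole_blood~dbs (K_b/d), estimated on a 21-adult cohort. Dashes in the DBS
columns mean the chemical was not quantifiable in dried blood spots (the
~50 uL spot volume raises detection limits sharply), so no coefficient
exists for those pairs.

The per-chemical lipophilicity entries (``log10_kow``, ``water_solubility``)
are SYNTHETIC placeholders: plausible values spanning the K_ow range of
these pollutant classes (2e4 to 4e8), assigned without regard to the
coefficients so that lipophilicity and the fitted coefficients are
unrelated by construction. They exist to exercise the biophysical partition
model, not to reproduce any chemical-specific property database.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import (
    ChemicalRecord,
    CompartmentComposition,
    DistributionFit,
    MATRICES,
    TargetLookupError,
)

#: Sample count behind every bundled coefficient.
TABLE_N = 21

#: Class-level instrumental detection limit ranges, ng/L.
#: plasma and whole blood share a range; DBS limits are higher.
IDL_CLASS_RANGES = {
    "pesticide_chc": {"plasma": (5.0, 30.0), "whole_blood": (5.0, 30.0), "dbs": (10.0, 120.0)},
    "pcb": {"plasma": (0.1, 0.9), "whole_blood": (0.1, 0.9), "dbs": (0.8, 22.0)},
    "bfr": {"plasma": (0.1, 30.0), "whole_blood": (0.1, 30.0), "dbs": (8.0, 200.0)},
}


def default_idl(chem_class: str, matrix: str) -> float:
    """Class-default IDL (ng/L): geometric midpoint of the class range."""
    lo, hi = IDL_CLASS_RANGES[chem_class][matrix]
    return math.sqrt(lo * hi)


# One row per chemical:
# (name, class,
#  r2_pw, beta_pw, se_pw,     plasma ~ whole_blood
#  r2_pd, beta_pd, se_pd,     plasma ~ dbs (None when not quantified in DBS)
#  r2_wd, beta_wd, se_wd,     whole_blood ~ dbs
#  wb_median,                 cohort whole-blood median, ng/L
#  log10_kow)                 synthetic lipophilicity placeholder
_TABLE = [
    ("pentachlorobenzene", "pesticide_chc", 0.73, 1.92, 0.10, None, None, None, None, None, None, 70.0, 4.3),
    ("alpha-HCH",          "pesticide_chc", 0.76, 1.83, 0.13, None, None, None, None, None, None, 5.0, 7.9),
    ("hexachlorobenzene",  "pesticide_chc", 0.96, 1.74, 0.03, 0.93, 1.80, 0.05, 0.99, 1.04, 0.01, 350.0, 5.2),
    ("beta-HCH",           "pesticide_chc", 1.00, 1.82, 0.02, 0.97, 1.87, 0.02, 0.99, 1.03, 0.01, 667.7, 6.8),
    ("dachtal",            "pesticide_chc", 0.94, 1.77, 0.06, None, None, None, None, None, None, 70.0, 4.7),
    ("trans-chlordane",    "pesticide_chc", 0.89, 2.26, 0.06, None, None, None, None, None, None, 20.0, 7.4),
    ("cis-chlordane",      "pesticide_chc", 0.93, 2.13, 0.07, None, None, None, None, None, None, 15.7, 5.9),
    ("trans-nonachlor",    "pesticide_chc", 0.91, 2.18, 0.07, 0.50, 2.18, 0.17, 0.63, 1.00, 0.07, 20.0, 8.3),
    ("p,p'-DDE",           "pesticide_chc", 0.96, 1.82, 0.05, 0.93, 1.87, 0.07, 0.95, 1.02, 0.03, 560.0, 5.0),
    ("cis-nonachlor",      "pesticide_chc", 0.80, 2.01, 0.08, None, None, None, None, None, None, 20.0, 7.1),
    ("PCB-110",            "pcb", 0.86, 1.63, 0.03, None, None, None, None, None, None, 0.68, 8.6),
    ("PCB-151",            "pcb", 0.91, 1.75, 0.03, 0.79, 1.86, 0.05, 0.91, 1.06, 0.02, 44.67, 4.5),
    ("PCB-135/144",        "pcb", 0.93, 1.71, 0.03, None, None, None, None, None, None, 9.69, 7.7),
    ("PCB-118",            "pcb", 0.91, 1.76, 0.03, 0.51, 2.08, 0.10, 0.47, 1.18, 0.06, 104.37, 5.6),
    ("PCB-132/153",        "pcb", 0.95, 1.72, 0.03, 0.94, 1.78, 0.03, 1.00, 1.04, 0.00, 67.98, 6.5),
    ("PCB-138/163",        "pcb", 0.96, 1.65, 0.02, 0.93, 1.67, 0.03, 0.99, 1.01, 0.01, 56.32, 4.9),
    ("PCB-175",            "pcb", 0.91, 1.69, 0.04, None, None, None, None, None, None, 11.65, 8.0),
    ("PCB-174",            "pcb", 0.85, 1.59, 0.05, None, None, None, None, None, None, 1.24, 5.4),
    ("PCB-202",            "pcb", 0.88, 1.74, 0.05, None, None, None, None, None, None, 1.26, 7.2),
    ("PCB-180",            "pcb", 0.80, 1.67, 0.03, 0.75, 1.66, 0.03, 0.97, 1.00, 0.01, 85.15, 6.1),
    ("PCB-170/190",        "pcb", 0.88, 1.74, 0.05, None, None, None, None, None, None, 4.82, 4.4),
    ("PCB-198",            "pcb", 0.80, 1.58, 0.05, None, None, None, None, None, None, 4.24, 6.9),
    ("TBBPa",              "bfr", 1.00, 1.75, 0.01, 0.89, 1.82, 0.06, 0.90, 1.04, 0.04, 75.34, 5.8),
    ("PBDE-28",            "bfr", 0.99, 1.60, 0.03, None, None, None, None, None, None, 10.86, 8.1),
    ("PBDE-75",            "bfr", 0.99, 1.68, 0.03, None, None, None, None, None, None, 23.41, 4.6),
    ("PBDE-47",            "bfr", 0.99, 1.67, 0.01, 0.97, 1.73, 0.02, 0.98, 1.04, 0.01, 593.43, 7.5),
    ("PBDE-66",            "bfr", 1.00, 1.67, 0.01, None, None, None, None, None, None, 107.76, 6.3),
    ("PBDE-100",           "bfr", 1.00, 1.66, 0.01, 0.95, 1.64, 0.04, 0.96, 0.99, 0.02, 85.87, 5.1),
    ("PBDE-99",            "bfr", 1.00, 1.65, 0.01, 0.99, 1.72, 0.01, 0.99, 1.04, 0.01, 81.27, 7.8),
    ("PBDE-85",            "bfr", 1.00, 1.66, 0.01, None, None, None, None, None, None, 59.69, 4.8),
    ("PBDE-154",           "bfr", 0.91, 1.66, 0.04, 0.89, 1.71, 0.05, 1.00, 1.03, 0.01, 119.42, 6.6),
    ("PBDE-153",           "bfr", 0.97, 1.61, 0.03, None, None, None, None, None, None, 5.55, 8.4),
]

_PAIR_SLOTS = {
    ("plasma", "whole_blood"): (2, 3, 4),
    ("plasma", "dbs"): (5, 6, 7),
    ("whole_blood", "dbs"): (8, 9, 10),
}


def builtin_coefficients() -> pd.DataFrame:
    """Bundled experimental distribution coefficients, one row per
    chemical per available ordered matrix pair.

    Columns: chemical, y_matrix, x_matrix, n, beta, se, r2, r2_est.
    ``r2_est`` is NaN: only the with-intercept R-squared is tabulated.
    """
    rows = []
    for entry in _TABLE:
        name = entry[0]
        for (y, x), (i_r2, i_beta, i_se) in _PAIR_SLOTS.items():
            if entry[i_beta] is None:
                continue
            rows.append(
                {
                    "chemical": name,
                    "y_matrix": y,
                    "x_matrix": x,
                    "n": TABLE_N,
                    "beta": entry[i_beta],
                    "se": entry[i_se],
                    "r2": entry[i_r2],
                    "r2_est": np.nan,
                }
            )
    return pd.DataFrame(rows)


def lookup_coefficient(chemical: str, y_matrix: str, x_matrix: str,
                       coefficients: pd.DataFrame | None = None) -> DistributionFit:
    """Look up one coefficient; raises :class:`TargetLookupError` if absent."""
    table = builtin_coefficients() if coefficients is None else coefficients
    hit = table[
        (table["chemical"] == chemical)
        & (table["y_matrix"] == y_matrix)
        & (table["x_matrix"] == x_matrix)
    ]
    if hit.empty:
        raise TargetLookupError(
            f"no coefficient for {chemical} ({y_matrix} ~ {x_matrix})"
        )
    row = hit.iloc[0]
    r2 = row.get("r2", np.nan)
    r2_est = row.get("r2_est", np.nan)
    return DistributionFit(
        chemical=chemical,
        y_matrix=y_matrix,
        x_matrix=x_matrix,
        n=int(row["n"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        r2=None if pd.isna(r2) else float(r2),
        r2_est=None if pd.isna(r2_est) else float(r2_est),
    )


def builtin_chemicals() -> pd.DataFrame:
    """Bundled chemical registry.

    Columns: chemical, chem_class, log10_kow, water_solubility_mg_per_L,
    idl_plasma, idl_whole_blood, idl_dbs. Lipophilicity/solubility columns
    are synthetic placeholders (see module docstring); IDLs are class
    defaults (geometric midpoints of the class ranges).
    """
    rows = []
    for entry in _TABLE:
        name, chem_class, log10_kow = entry[0], entry[1], entry[12]
        rows.append(
            {
                "chemical": name,
                "chem_class": chem_class,
                "log10_kow": log10_kow,
                # synthetic: solubility declines with lipophilicity
                "water_solubility_mg_per_L": round(10 ** (1.2 - 0.4 * log10_kow), 6),
                "idl_plasma": default_idl(chem_class, "plasma"),
                "idl_whole_blood": default_idl(chem_class, "whole_blood"),
                "idl_dbs": default_idl(chem_class, "dbs"),
            }
        )
    return pd.DataFrame(rows)


def builtin_wb_medians() -> dict:
    """Cohort whole-blood median concentration (ng/L) per chemical."""
    return {entry[0]: entry[11] for entry in _TABLE}


# Cohort whole-blood summary statistics (ng/L): chemical -> (mean, SD).
# Together with the medians these parameterize the paper-like cohort
# preset's lognormal marginals by moment matching.
_WB_STATS = {
    "pentachlorobenzene": (68.2, 22.0),
    "alpha-HCH": (7.6, 4.4),
    "hexachlorobenzene": (350.8, 183.2),
    "beta-HCH": (654.7, 242.6),
    "dachtal": (74.7, 55.5),
    "trans-chlordane": (20.2, 6.9),
    "cis-chlordane": (17.3, 8.9),
    "trans-nonachlor": (19.7, 10.5),
    "p,p'-DDE": (529.8, 401.0),
    "cis-nonachlor": (17.8, 9.3),
    "PCB-110": (0.75, 0.20),
    "PCB-151": (45.83, 13.29),
    "PCB-135/144": (9.26, 2.47),
    "PCB-118": (111.48, 36.33),
    "PCB-132/153": (76.51, 28.11),
    "PCB-138/163": (65.91, 24.11),
    "PCB-175": (11.04, 4.62),
    "PCB-174": (1.20, 0.45),
    "PCB-202": (1.13, 0.38),
    "PCB-180": (88.50, 15.45),
    "PCB-170/190": (5.08, 2.28),
    "PCB-198": (4.07, 1.26),
    "TBBPa": (90.16, 49.81),
    "PBDE-28": (13.53, 11.16),
    "PBDE-75": (29.30, 32.15),
    "PBDE-47": (628.16, 229.13),
    "PBDE-66": (115.29, 71.00),
    "PBDE-100": (68.72, 35.30),
    "PBDE-99": (75.67, 22.53),
    "PBDE-85": (54.13, 44.86),
    "PBDE-154": (106.68, 46.77),
    "PBDE-153": (6.01, 4.15),
}


def builtin_wb_stats() -> dict:
    """Cohort whole-blood (mean, SD) in ng/L per chemical."""
    return dict(_WB_STATS)


def wb_gsd(name: str) -> float:
    """Geometric SD implied by the bundled whole-blood mean/SD via
    lognormal moment matching: GSD = exp(sqrt(ln(1 + CV^2)))."""
    mean, sd = _WB_STATS[name]
    cv = sd / mean
    return math.exp(math.sqrt(math.log1p(cv * cv)))


def chemical_record(name: str) -> ChemicalRecord:
    """Registry row as a :class:`ChemicalRecord` (with class-default IDLs)."""
    table = builtin_chemicals().set_index("chemical")
    if name not in table.index:
        raise TargetLookupError(f"unknown chemical {name!r}")
    row = table.loc[name]
    return ChemicalRecord(
        name=name,
        chem_class=row["chem_class"],
        log10_kow=float(row["log10_kow"]),
        water_solubility=float(row["water_solubility_mg_per_L"]),
        idl={m: float(row[f"idl_{m}"]) for m in MATRICES},
    )


def summary_group(name: str, chem_class: str) -> str:
    """Reporting group for class summaries.

    Brominated flame retardants split into PBDE congeners and
    tetrabromobisphenol A (its own single-member group).
    """
    if chem_class == "bfr":
        return "tbbpa" if name == "TBBPa" else "pbde"
    return chem_class


#: Whole-blood composition (mass fractions) used by the partition model.
WHOLE_BLOOD_COMPOSITION = CompartmentComposition(
    name="whole_blood", neutral_lipid=0.0044, phospholipid=0.0021, water=0.80
)

#: Liver composition for the worked tissue/blood comparison.
LIVER_COMPOSITION = CompartmentComposition(
    name="liver", neutral_lipid=0.0281, phospholipid=0.0389, water=0.72
)

#: SYNTHETIC plasma composition. The plasma lipid/water fractions behind the
#: published model predictions are cited from the literature but not
#: tabulated with the model, so this default is a stand-in chosen to give
#: plasma/whole-blood predictions near 1.05 (the neighbourhood the model
#: produces for lipophilic compounds); replace via configuration for real use.
PLASMA_COMPOSITION_SYNTHETIC = CompartmentComposition(
    name="plasma_synthetic", neutral_lipid=0.0046, phospholipid=0.0023, water=0.95
)
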