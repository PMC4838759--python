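"""CSV readers/writers and configuration for the package's tabular formats.

All concentrations are ng/L internally. Files carrying a ``units`` column
must say ``ng/L``; anything else is rejected rather than silently converted.
Missing values are empty cells and are distinct from below-IDL measurements,
which carry a real (censored) number plus the ``below_idl`` flag.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    CHEM_CLASSES,
    EDUCATION_LEVELS,
    MATRICES,
    RACE_LEVELS,
    SEX_LEVELS,
    SMOKING_LEVELS,
    SchemaError,
    ValidationError,
)

log = logging.getLogger("popblood")

PANEL_COLUMNS = [
    "participant_id",
    "chemical",
    "matrix",
    "replicate",
    "concentration_ng_per_L",
    "below_idl",
]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_years",
    "sex",
    "race",
    "education",
    "smoking",
]
CHEMICAL_COLUMNS = [
    "chemical",
    "chem_class",
    "log10_kow",
    "water_solubility_mg_per_L",
    "idl_plasma",
    "idl_whole_blood",
    "idl_dbs",
]
COEFFICIENT_COLUMNS = ["chemical", "y_matrix", "x_matrix", "n", "beta", "se", "r2", "r2_est"]


def setup_logging(verbose: bool = False) -> None:
    """Configure stderr logging for the CLI."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _require_columns(df: pd.DataFrame, required: list, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def _check_units_column(df: pd.DataFrame, what: str) -> None:
    if "units" in df.columns:
        bad = set(df["units"].dropna().unique()) - {"ng/L"}
        if bad:
            raise SchemaError(f"{what}: unsupported units {sorted(bad)}; expected ng/L")


def load_panel(path) -> pd.DataFrame:
    """Read a long-format concentration panel.

    Required columns: participant_id, chemical, matrix, replicate,
    concentration_ng_per_L, below_idl. Matrix labels outside
    plasma/whole_blood/dbs (e.g. serum, which is not modelled) are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, f"panel {path}")
    _check_units_column(df, f"panel {path}")
    unknown = set(df["matrix"].unique()) - set(MATRICES)
    if unknown:
        raise SchemaError(
            f"panel {path}: unknown matrix labels {sorted(unknown)}; "
            f"expected one of {MATRICES}"
        )
    conc = pd.to_numeric(df["concentration_ng_per_L"], errors="coerce")
    negative = df.index[conc < 0]
    if len(negative):
        raise ValidationError(
            f"panel {path}: negative concentration at row {negative[0]}"
        )
    df["concentration_ng_per_L"] = conc
    df["below_idl"] = df["below_idl"].astype(bool)
    df["participant_id"] = df["participant_id"].astype(str)
    return df[[c for c in df.columns]]


def write_panel(panel: pd.DataFrame, path) -> None:
    _require_columns(panel, PANEL_COLUMNS, "panel")
    panel.to_csv(path, index=False)


def load_participants(path) -> pd.DataFrame:
    """Read a participant covariate table, validating levels and adult age."""
    df = pd.read_csv(path)
    _require_columns(df, PARTICIPANT_COLUMNS, f"participants {path}")
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("race", RACE_LEVELS),
        ("education", EDUCATION_LEVELS),
        ("smoking", SMOKING_LEVELS),
    ):
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise SchemaError(
                f"participants {path}: {col} has unknown levels {sorted(bad)}"
            )
    if (df["age_years"] < 18).any():
        raise ValidationError(f"participants {path}: ages below 18 present")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_participants(df: pd.DataFrame, path) -> None:
    _require_columns(df, PARTICIPANT_COLUMNS, "participants")
    df.to_csv(path, index=False)


def load_chemicals(path) -> pd.DataFrame:
    """Read a chemical registry (class, lipophilicity, per-matrix IDLs)."""
    df = pd.read_csv(path)
    _require_columns(df, ["chemical", "chem_class"], f"chemicals {path}")
    bad = set(df["chem_class"].dropna().unique()) - set(CHEM_CLASSES)
    if bad:
        raise SchemaError(f"chemicals {path}: unknown chem_class {sorted(bad)}")
    for col in CHEMICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    for m in MATRICES:
        col = f"idl_{m}"
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals <= 0).any():
            raise ValidationError(f"chemicals {path}: non-positive IDL in {col}")
    return df[CHEMICAL_COLUMNS]


def write_chemicals(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["chemical", "chem_class"], "chemicals")
    df.to_csv(path, index=False)


def load_coefficients(path) -> pd.DataFrame:
    """Read a distribution-coefficient table (fitted or bundled format)."""
    df = pd.read_csv(path)
    _require_columns(df, ["chemical", "y_matrix", "x_matrix", "beta"], f"coefficients {path}")
    for col in ("y_matrix", "x_matrix"):
        bad = set(df[col].unique()) - set(MATRICES)
        if bad:
            raise SchemaError(f"coefficients {path}: unknown matrix {sorted(bad)}")
    if (df["beta"] <= 0).any():
        raise ValidationError(f"coefficients {path}: non-positive beta present")
    return df


def write_coefficients(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["chemical", "y_matrix", "x_matrix", "beta"], "coefficients")
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def idl_lookup(chemicals: pd.DataFrame) -> dict:
    """Map (chemical, matrix) -> IDL ng/L from a chemicals table.

    Entries left blank fall back to the class-default IDL.
    """
    from .registry import default_idl

    table = {}
    for _, row in chemicals.iterrows():
        for m in MATRICES:
            val = row.get(f"idl_{m}")
            if pd.isna(val):
                val = default_idl(row["chem_class"], m)
            table[(row["chemical"], m)] = float(val)
    return table
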