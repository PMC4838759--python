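"""Synthetic cohorts with the partitioning, noise, and censoring structure
the analysis assumes.

The generative model, per participant i and chemical c:

* latent whole-blood concentration ``B`` ~ lognormal(GM, GSD);
* latent plasma concentration ``K_pb * B * exp(eps)`` with ``eps`` zero-mean
  normal on the log scale, SD ``ratio_noise_cv`` (participant-level spread of
  the plasma/blood ratio around the distribution coefficient);
* latent DBS concentration ``(B / K_bd) * exp(delta)``, SD ``dbs_noise_cv``
  (DBS tracks whole blood with a coefficient near one);
* each instrumental replicate multiplies the latent value by
  ``exp(replicate_cv * z)`` — multiplicative so concentrations stay
  positive, and equal to ``1 + error`` to first order at the 3% replicate
  CV typical of these assays.

Replicate counts default to 2 for plasma and whole blood and 3 for DBS.
Values below the matrix IDL are flagged ``below_idl`` and left at their raw
value; the half-IDL substitution is a downstream cleaning step.

Covariate effects, when requested, shift the participant-level log-ratio
``eps`` additively, so a positive shift scales the plasma/blood ratio of
that subgroup multiplicatively. For Table-3-style checks on the natural
ratio scale use :func:`simulate_ratio_study`, which generates per-participant
plasma/whole-blood ratios with additive natural-scale covariate effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import MATRICES, TargetLookupError, ValidationError
from .io import CHEMICAL_COLUMNS
from .registry import (
    builtin_chemicals,
    builtin_coefficients,
    builtin_wb_medians,
    default_idl,
)

#: Replicates analyzed per matrix.
DEFAULT_REPLICATES = {"plasma": 2, "whole_blood": 2, "dbs": 3}

#: Cohort covariate margins used by the default participant generator:
#: fraction male, white, holding a graduate degree, and never-smokers.
COHORT_MARGINS = {"male": 12 / 21, "white": 16 / 21, "masters": 14 / 21, "never": 16 / 21}


@dataclass(frozen=True)
class ChemicalSim:
    """Generating parameters for one chemical."""

    name: str
    chem_class: str = "pcb"
    gm_blood: float = 100.0       # geometric mean whole-blood concentration, ng/L
    gsd_blood: float = 1.5        # geometric SD (dimensionless, >= 1)
    k_pb: float = 1.7             # true plasma/whole-blood coefficient
    k_bd: float = 1.0             # true whole-blood/DBS coefficient
    ratio_noise_cv: Optional[float] = None   # falls back to the spec default
    dbs_noise_cv: Optional[float] = None
    idl: dict = field(default_factory=dict)  # matrix -> ng/L; class default if absent

    def __post_init__(self):
        if not self.gm_blood > 0:
            raise ValidationError(f"{self.name}: gm_blood must be > 0")
        if not self.gsd_blood >= 1:
            raise ValidationError(f"{self.name}: gsd_blood must be >= 1")
        if not (self.k_pb > 0 and self.k_bd > 0):
            raise ValidationError(f"{self.name}: coefficients must be > 0")
        for cv in (self.ratio_noise_cv, self.dbs_noise_cv):
            if cv is not None and cv < 0:
                raise ValidationError(f"{self.name}: noise CV must be >= 0")

    def idl_for(self, matrix: str) -> float:
        return self.idl.get(matrix, default_idl(self.chem_class, matrix))


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic cohort."""

    chemicals: Sequence[ChemicalSim]
    n_participants: int = 21
    seed: Optional[int] = None
    replicate_cv: float = 0.03
    ratio_noise_cv: float = 0.05
    dbs_noise_cv: float = 0.03
    replicates: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    # chemical -> {"age": slope, "sex:male": shift, "race:other": ..., ...}
    # applied additively to the participant log-ratio
    covariate_effects: dict = field(default_factory=dict)
    # (chemical, participant_id, multiplier) plasma outlier injections
    outliers: Sequence[tuple] = ()

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for cv in (self.replicate_cv, self.ratio_noise_cv, self.dbs_noise_cv):
            if cv < 0:
                raise ValidationError("noise CVs must be >= 0")


def calibrate_ratio_noise(beta: float, se: float, n: int, replicate_cv: float = 0.03,
                          n_rep_y: int = 2, n_rep_x: int = 2) -> float:
    """Participant-level log-ratio SD that makes a through-origin fit's
    standard error match ``se`` at sample size ``n``.

    For y = beta * x * exp(eps), the fitted SE is approximately
    ``beta * sigma_total / sqrt(n - 1)`` where ``sigma_total`` pools the
    ratio noise with averaged replicate noise on both axes; inverting and
    removing the replicate contributions gives the ratio SD.
    """
    if not (beta > 0 and se >= 0 and n >= 2):
        raise ValidationError("need beta > 0, se >= 0, n >= 2")
    total_var = (se * math.sqrt(n - 1) / beta) ** 2
    rep_var = replicate_cv**2 / n_rep_y + replicate_cv**2 / n_rep_x
    return math.sqrt(max(total_var - rep_var, 0.0))


def paper_like_spec(seed: Optional[int] = None, chemicals: Optional[Sequence[str]] = None,
                    gsd_blood: Optional[float] = None,
                    replicate_cv: float = 0.03) -> SimulationSpec:
    """Cohort preset mirroring the study conditions.

    Geometric means come from the bundled cohort whole-blood medians, the
    generating coefficients from the bundled registry, per-chemical
    geometric SDs from lognormal moment matching of the bundled
    whole-blood mean/SD summaries (override with ``gsd_blood`` to force a
    common spread), and each chemical's ratio noise is calibrated so the
    fitted standard error at n = 21 matches the bundled SE.
    """
    from .registry import wb_gsd

    coeffs = builtin_coefficients()
    classes = builtin_chemicals().set_index("chemical")["chem_class"]
    medians = builtin_wb_medians()
    names = list(medians) if chemicals is None else list(chemicals)
    sims = []
    reps = DEFAULT_REPLICATES
    for name in names:
        pw = coeffs[(coeffs["chemical"] == name) & (coeffs["x_matrix"] == "whole_blood")]
        wd = coeffs[
            (coeffs["chemical"] == name)
            & (coeffs["y_matrix"] == "whole_blood")
            & (coeffs["x_matrix"] == "dbs")
        ]
        if pw.empty:
            raise TargetLookupError(f"{name!r} has no bundled plasma~whole_blood entry")
        k_pb, se_pb, n = float(pw.iloc[0]["beta"]), float(pw.iloc[0]["se"]), int(pw.iloc[0]["n"])
        ratio_cv = calibrate_ratio_noise(k_pb, se_pb, n, replicate_cv,
                                         reps["plasma"], reps["whole_blood"])
        if wd.empty:
            k_bd, dbs_cv = 1.0, 0.03
        else:
            k_bd, se_bd = float(wd.iloc[0]["beta"]), float(wd.iloc[0]["se"])
            dbs_cv = calibrate_ratio_noise(k_bd, se_bd, n, replicate_cv,
                                           reps["whole_blood"], reps["dbs"])
        sims.append(
            ChemicalSim(
                name=name,
                chem_class=str(classes[name]),
                gm_blood=medians[name],
                gsd_blood=wb_gsd(name) if gsd_blood is None else gsd_blood,
                k_pb=k_pb,
                k_bd=k_bd,
                ratio_noise_cv=ratio_cv,
                dbs_noise_cv=dbs_cv,
            )
        )
    return SimulationSpec(chemicals=tuple(sims), seed=seed, replicate_cv=replicate_cv)


def generate_participants(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Participant table with the cohort's covariate margins.

    Ages are drawn uniformly over 29-65 years; binary covariates are
    assigned at the cohort proportions (rounded counts, shuffled), so a
    default 21-participant cohort reproduces the study margins exactly.
    """
    def levels(p_ref_complement, level_hi, level_lo):
        k = int(round(p_ref_complement * n))
        arr = np.array([level_hi] * k + [level_lo] * (n - k), dtype=object)
        rng.shuffle(arr)
        return arr

    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:02d}" for i in range(n)],
            "age_years": rng.integers(29, 66, size=n),
            "sex": levels(COHORT_MARGINS["male"], "male", "female"),
            "race": levels(1 - COHORT_MARGINS["white"], "other", "white"),
            "education": levels(1 - COHORT_MARGINS["masters"], "below_masters", "masters_or_above"),
            "smoking": levels(1 - COHORT_MARGINS["never"], "former_or_current", "never"),
        }
    )


def _covariate_shift(effects: dict, row: pd.Series) -> float:
    shift = 0.0
    for key, value in effects.items():
        if key == "age":
            shift += value * float(row["age_years"])
        else:
            covariate, level = key.split(":", 1)
            if str(row[covariate]) == level:
                shift += value
    return shift


def simulate_cohort(spec: SimulationSpec, participants: Optional[pd.DataFrame] = None):
    """Generate one synthetic cohort.

    Returns ``(panel, participants, chemicals, truth)``: the long-format
    replicate-level concentration panel, the covariate table, a chemicals
    registry (class, IDLs, placeholder lipophilicity where known), and a
    truth table holding every generating value (latent concentrations per
    participant and the per-chemical parameters).
    """
    rng = np.random.default_rng(spec.seed)
    if participants is None:
        participants = generate_participants(spec.n_participants, rng)
    n = len(participants)

    reg = builtin_chemicals().set_index("chemical")
    panel_rows, truth_rows, chem_rows = [], [], []
    for chem in spec.chemicals:
        sigma_b = math.log(chem.gsd_blood)
        ratio_cv = spec.ratio_noise_cv if chem.ratio_noise_cv is None else chem.ratio_noise_cv
        dbs_cv = spec.dbs_noise_cv if chem.dbs_noise_cv is None else chem.dbs_noise_cv

        blood = chem.gm_blood * np.exp(sigma_b * rng.standard_normal(n))
        eps = ratio_cv * rng.standard_normal(n)
        delta = dbs_cv * rng.standard_normal(n)
        effects = spec.covariate_effects.get(chem.name)
        if effects:
            eps = eps + np.array(
                [_covariate_shift(effects, row) for _, row in participants.iterrows()]
            )
        latent = {
            "whole_blood": blood,
            "plasma": chem.k_pb * blood * np.exp(eps),
            "dbs": (blood / chem.k_bd) * np.exp(delta),
        }
        for i, pid in enumerate(participants["participant_id"]):
            for matrix in MATRICES:
                idl = chem.idl_for(matrix)
                n_rep = spec.replicates.get(matrix, 2)
                noise = np.exp(spec.replicate_cv * rng.standard_normal(n_rep))
                values = latent[matrix][i] * noise
                for r, value in enumerate(values, start=1):
                    panel_rows.append(
                        (pid, chem.name, matrix, r, value, bool(value < idl))
                    )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "chemical": chem.name,
                    "blood_latent": latent["whole_blood"][i],
                    "plasma_latent": latent["plasma"][i],
                    "dbs_latent": latent["dbs"][i],
                    "k_pb": chem.k_pb,
                    "k_bd": chem.k_bd,
                    "gm_blood": chem.gm_blood,
                    "gsd_blood": chem.gsd_blood,
                    "ratio_noise_cv": ratio_cv,
                    "dbs_noise_cv": dbs_cv,
                    "replicate_cv": spec.replicate_cv,
                    "outlier_multiplier": 1.0,
                }
            )
        if chem.name in reg.index:
            row = reg.loc[chem.name].to_dict()
            row["chemical"] = chem.name
        else:
            row = {
                "chemical": chem.name,
                "chem_class": chem.chem_class,
                "log10_kow": np.nan,
                "water_solubility_mg_per_L": np.nan,
            }
        for m in MATRICES:
            row[f"idl_{m}"] = chem.idl_for(m)
        chem_rows.append({c: row.get(c) for c in CHEMICAL_COLUMNS})

    panel = pd.DataFrame(
        panel_rows,
        columns=[
            "participant_id",
            "chemical",
            "matrix",
            "replicate",
            "concentration_ng_per_L",
            "below_idl",
        ],
    )
    truth = pd.DataFrame(truth_rows)
    chemicals = pd.DataFrame(chem_rows)
    for chemical, participant, multiplier in spec.outliers:
        panel = inject_outlier(panel, chemical, participant, multiplier, truth=truth)
    return panel, participants, chemicals, truth


def inject_outlier(panel: pd.DataFrame, chemical: str, participant: str,
                   multiplier: float, truth: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Multiply one participant's plasma values for one chemical.

    Emulates the single gross outliers seen in real panels. Provenance is
    recorded in ``truth`` (in place) when a truth table is supplied.
    """
    mask = (
        (panel["chemical"] == chemical)
        & (panel["participant_id"] == participant)
        & (panel["matrix"] == "plasma")
    )
    if not mask.any():
        raise TargetLookupError(
            f"no plasma rows for chemical={chemical!r}, participant={participant!r}"
        )
    panel = panel.copy()
    panel.loc[mask, "concentration_ng_per_L"] *= multiplier
    if truth is not None:
        tmask = (truth["chemical"] == chemical) & (truth["participant_id"] == participant)
        truth.loc[tmask, "outlier_multiplier"] *= multiplier
    return panel


def simulate_ratio_study(effects: dict, noise_sd: float = 0.2, base: float = 1.8,
                         n: int = 21, seed: Optional[int] = None,
                         participants: Optional[pd.DataFrame] = None):
    """Per-participant plasma/whole-blood ratios with additive natural-scale
    covariate effects, for exercising the covariate regression.

    ``effects`` uses the same keys as the cohort generator (``"age"`` slope
    plus ``"covariate:level"`` shifts); the ratio for participant i is
    ``base + sum(effects) + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    if participants is None:
        participants = generate_participants(n, rng)
    shifts = np.array([_covariate_shift(effects, row) for _, row in participants.iterrows()])
    ratios = base + shifts + noise_sd * rng.standard_normal(len(participants))
    table = pd.DataFrame(
        {
            "participant_id": participants["participant_id"],
            "ratio": ratios,
            "substituted": False,
        }
    )
    return table, participants
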