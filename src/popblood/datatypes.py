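"""Domain types shared across the package.

Concentration panels, participant tables and chemical registries travel as
pandas DataFrames with fixed column schemas (see :mod:`popblood.io`); the
dataclasses here hold per-record metadata and fitted results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Blood matrices modelled by the package. Serum is deliberately absent: it
#: was never measured and no serum coefficient exists.
MATRICES = ("plasma", "whole_blood", "dbs")

#: Chemical classes of the persistent organic pollutants handled here.
CHEM_CLASSES = ("pesticide_chc", "pcb", "bfr")

#: Ordered matrix pairs (y_matrix, x_matrix) for distribution fits:
#: K_p/b, K_p/d, K_b/d.
DEFAULT_PAIRS = (
    ("plasma", "whole_blood"),
    ("plasma", "dbs"),
    ("whole_blood", "dbs"),
)

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "other")
EDUCATION_LEVELS = ("masters_or_above", "below_masters")
SMOKING_LEVELS = ("never", "former_or_current")


class SchemaError(ValueError):
    """A table is missing a required column or carries an unknown label."""


class ValidationError(ValueError):
    """A table row violates a domain invariant (e.g. negative concentration)."""


class ConfigurationError(ValueError):
    """Required configuration (e.g. an IDL for a chemical/matrix) is absent."""


class DegenerateDataError(ValueError):
    """The data admit no estimate (all-zero regressor, empty compartment)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


class PolicyError(ValueError):
    """A conversion fallback that the recommendations forbid was requested."""


class TargetLookupError(KeyError):
    """A requested chemical/participant/pair is not present."""


@dataclass(frozen=True)
class ChemicalRecord:
    """One persistent organic pollutant.

    Parameters
    ----------
    name
        Chemical identifier (e.g. ``"beta-HCH"``, ``"PCB-118"``).
    chem_class
        One of ``pesticide_chc``, ``pcb``, ``bfr``.
    log10_kow
        log10 octanol-water distribution coefficient (dimensionless).
    water_solubility
        Solubility in water, mg/L.
    idl
        Instrumental detection limit per matrix, ng/L. Missing matrices fall
        back to the class-default IDL (geometric midpoint of the class range).
    """

    name: str
    chem_class: str
    log10_kow: Optional[float] = None
    water_solubility: Optional[float] = None
    idl: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"unknown chem_class {self.chem_class!r} for {self.name}"
            )
        if self.water_solubility is not None and not self.water_solubility > 0:
            raise ValidationError(f"water_solubility must be > 0 for {self.name}")
        for matrix, value in self.idl.items():
            if matrix not in MATRICES:
                raise SchemaError(f"unknown matrix {matrix!r} in IDL map of {self.name}")
            if not value > 0:
                raise ValidationError(f"IDL must be > 0 ({self.name}, {matrix})")


@dataclass(frozen=True)
class Participant:
    """One adult study participant with the covariates modelled downstream."""

    participant_id: str
    age: float
    sex: str
    race: str
    education: str
    smoking: str

    def __post_init__(self):
        if self.age < 18:
            raise ValidationError(
                f"participant {self.participant_id}: age {self.age} < 18"
            )
        for value, levels, name in (
            (self.sex, SEX_LEVELS, "sex"),
            (self.race, RACE_LEVELS, "race"),
            (self.education, EDUCATION_LEVELS, "education"),
            (self.smoking, SMOKING_LEVELS, "smoking"),
        ):
            if value not in levels:
                raise ValidationError(
                    f"participant {self.participant_id}: {name}={value!r} "
                    f"not in {levels}"
                )


@dataclass(frozen=True)
class DistributionFit:
    """A fitted matrix-pair distribution coefficient.

    ``beta`` is the through-origin regression slope (the distribution
    coefficient K); ``r2_est`` is the no-intercept goodness-of-fit statistic
    1 - SSE_no_intercept / SST_corrected, where SST_corrected is the
    with-intercept model's corrected total sum of squares. ``r2`` and the
    ``intercept_*`` fields describe the companion with-intercept fit.
    """

    chemical: str
    y_matrix: str
    x_matrix: str
    n: int
    beta: float
    se: float
    r2: Optional[float] = None
    r2_est: Optional[float] = None
    intercept_beta: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept: Optional[float] = None
    low_reliability: bool = False

    @property
    def pair(self) -> tuple:
        return (self.y_matrix, self.x_matrix)


@dataclass(frozen=True)
class CompartmentComposition:
    """Neutral-lipid / phospholipid / water mass fractions of a compartment."""

    name: str
    neutral_lipid: float
    phospholipid: float
    water: float

    def __post_init__(self):
        for frac, label in (
            (self.neutral_lipid, "neutral_lipid"),
            (self.phospholipid, "phospholipid"),
            (self.water, "water"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{self.name}: {label}={frac} outside [0, 1]")
        if self.neutral_lipid + self.phospholipid + self.water > 1.0 + 1e-12:
            raise ValidationError(f"{self.name}: fractions sum to more than 1")


@dataclass(frozen=True)
class MassBalanceParams:
    """Plasma weight fraction of whole blood and its effective value.

    ``plasma_weight_fraction`` (default 0.55) bounds the plasma/whole-blood
    concentration ratio at 1/w_p when all analyte mass resides in plasma.
    ``effective_plasma_fraction`` (default 0.45) is the value that
    reconciles that bound with the experimental coefficients.
    """

    plasma_weight_fraction: float = 0.55
    effective_plasma_fraction: float = 0.45

    def __post_init__(self):
        for value, label in (
            (self.plasma_weight_fraction, "plasma_weight_fraction"),
            (self.effective_plasma_fraction, "effective_plasma_fraction"),
        ):
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{label}={value} outside (0, 1)")


@dataclass(frozen=True)
class ConversionResult:
    """Result of converting one concentration between matrices."""

    chemical: str
    from_matrix: str
    to_matrix: str
    input_concentration: float
    converted_concentration: float
    relative_se: float
    source: str  # fitted | bundled_table | class_average | identity | unity_dbs
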