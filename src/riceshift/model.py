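"""Shared domain types, controlled vocabularies and unit conventions.

The pipeline operates on per-capita daily nutrient supplies for three B
vitamins, stratified by country, sex and 5-year age bin.  Folate is carried
in micrograms per day, thiamin and riboflavin in milligrams per day; the
unit is validated wherever a table states it, never silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass

NUTRIENTS: tuple[str, ...] = ("folate", "thiamin", "riboflavin")

#: canonical unit per nutrient (amount per person per day)
UNITS: dict[str, str] = {"folate": "ug", "thiamin": "mg", "riboflavin": "mg"}

SEXES: tuple[str, ...] = ("female", "male")

#: foods carrying nutrient supply in the synthetic world; the first three
#: are the industrially fortifiable grain vehicles, "other" is the rest of
#: the diet.
FOODS: tuple[str, ...] = ("rice", "wheat flour", "maize flour", "other")

VEHICLES: tuple[str, ...] = ("wheat flour", "rice", "maize flour")

STATES: tuple[str, ...] = ("none", "pregnant", "lactating")

MEASURES: tuple[str, ...] = ("deaths", "dalys")

#: lower edges of the 5-year age bins; 80 means 80+
AGE_BINS: tuple[int, ...] = tuple(range(0, 85, 5))

#: female reproductive-age bins (15-49)
REPRO_AGE_BINS: tuple[int, ...] = tuple(range(15, 50, 5))

#: fraction of a year spent pregnant per birth (40 of 52 weeks)
PREGNANCY_YEAR_FRACTION: float = 40.0 / 52.0


class RiceshiftError(Exception):
    """Base class for all package errors."""


class SchemaError(RiceshiftError):
    """A table's header does not match its declared schema."""


class ValidationError(RiceshiftError):
    """A table row violates a type invariant."""


class DomainError(RiceshiftError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class ConfigError(RiceshiftError):
    """An invalid configuration value."""


class CoverageError(RiceshiftError):
    """A lookup table fails to cover a required key or age bin."""


class FitError(RiceshiftError):
    """A curve or distribution fit failed or is infeasible."""


class NumericError(RiceshiftError):
    """A numerical routine failed to converge."""


@dataclass(frozen=True)
class AgeSexStratum:
    """One country / sex / 5-year-age-bin cell of the population."""

    country_code: str
    sex: str
    age_low: int
    population: float
    year: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex code {self.sex!r}")
        if self.age_low not in AGE_BINS:
            raise ValidationError(f"age_low {self.age_low} not a 5-year bin edge")
        if self.population < 0:
            raise ValidationError(f"negative population {self.population}")


@dataclass(frozen=True)
class NutrientSupplyRecord:
    """Per-capita daily supply of one nutrient from one food in one stratum."""

    stratum: AgeSexStratum
    food: str
    nutrient: str
    supply: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValidationError(f"unknown nutrient {self.nutrient!r}")
        if self.supply < 0:
            raise ValidationError(f"negative supply {self.supply}")
        if self.se is not None and self.se < 0:
            raise ValidationError(f"negative se {self.se}")


@dataclass(frozen=True)
class UncertainQuantity:
    """A reported mean with a 95% confidence interval.

    The Monte Carlo layer attaches a skew-normal sampler matched to the
    triple; here it is only the validated container.
    """

    mean: float
    lo95: float
    hi95: float

    def __post_init__(self) -> None:
        if not (self.lo95 <= self.mean <= self.hi95):
            raise ValidationError(
                f"interval ({self.lo95}, {self.hi95}) does not bracket mean {self.mean}"
            )

    @property
    def degenerate(self) -> bool:
        return self.lo95 == self.mean == self.hi95


@dataclass(frozen=True)
class BurdenRecord:
    """Annual national burden (deaths or DALYs) of neural tube defects."""

    country_code: str
    measure: str
    value: UncertainQuantity

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown burden measure {self.measure!r}")
        if self.value.mean < 0:
            raise ValidationError("burden mean must be >= 0")


@dataclass(frozen=True)
class CO2LossFactor:
    """Fractional change of one nutrient's density in rice under ~580 ppm CO2.

    Negative values are losses.  Monte Carlo samples are clamped to [-1, 1].
    """

    nutrient: str
    frac_change: UncertainQuantity

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValidationError(f"unknown nutrient {self.nutrient!r}")
        if not -1.0 <= self.frac_change.mean <= 1.0:
            raise ValidationError("mean fractional change must lie in [-1, 1]")


@dataclass(frozen=True)
class IntakeDistribution:
    """Normal model of usual intake in a stratum: mean and CV (default 30%)."""

    mean: float
    cv: float = 0.30

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise DomainError(f"intake mean must be > 0, got {self.mean}")
        if self.cv <= 0:
            raise DomainError(f"cv must be > 0, got {self.cv}")

    @property
    def sd(self) -> float:
        return self.cv * self.mean

    def scaled(self, ratio: float) -> "IntakeDistribution":
        """Multiplicative shift of the whole distribution; CV is preserved."""
        if ratio <= 0:
            raise DomainError(f"ratio must be > 0, got {ratio}")
        return IntakeDistribution(self.mean * ratio, self.cv)


@dataclass(frozen=True)
class ReproductiveProfile:
    """Fractions of women in a stratum who are pregnant / lactating / neither."""

    frac_pregnant: float
    frac_lactating: float

    def __post_init__(self) -> None:
        if self.frac_pregnant < 0 or self.frac_lactating < 0:
            raise DomainError("state fractions must be >= 0")
        if self.frac_pregnant + self.frac_lactating > 1 + 1e-12:
            raise DomainError("pregnant + lactating fractions exceed 1")

    @property
    def frac_neither(self) -> float:
        return 1.0 - self.frac_pregnant - self.frac_lactating
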