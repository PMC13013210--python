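"""Scalar Summer Simmer Index (SSI) mathematics.

The SSI is an apparent-temperature index on the Fahrenheit scale that
combines air temperature ``Ta`` (degF) and relative humidity ``Ur`` (%)
to express perceived summer heat stress::

    SSI = 1.98 * [Ta - (0.55 - 0.0055 * Ur) * (Ta - 58)] - 56.83

At ``Ta = 58`` degF the humidity term vanishes; above 58 degF higher
humidity raises the perceived temperature, below it the effect reverses.
SSI values are interpreted through an ordered table of half-open
intervals (thermal-comfort categories) that always operate on the
Fahrenheit-scale value, regardless of the display unit.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Unit",
    "FormulaConstants",
    "ComfortCategory",
    "ClassificationScheme",
    "ConfigurationError",
    "ValidationError",
    "convert_temperature",
    "compute_ssi",
    "compute_ssi_units",
    "classify_ssi",
    "table1_scheme",
    "sixclass_scheme",
]

ABSOLUTE_ZERO_C = -273.15
ABSOLUTE_ZERO_F = -459.67


class ConfigurationError(ValueError):
    """Bad configuration: unknown unit, malformed scheme, ..."""


class ValidationError(ValueError):
    """Input data outside its physical domain."""


class Unit(enum.Enum):
    """Temperature unit selector (mirrors the input/output unit choice)."""

    CELSIUS = "C"
    FAHRENHEIT = "F"

    @classmethod
    def coerce(cls, value: "Unit | str") -> "Unit":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper().strip().lstrip("°")[:1])
        except ValueError:
            raise ConfigurationError(f"unknown temperature unit: {value!r}") from None


@dataclass(frozen=True)
class FormulaConstants:
    """Coefficients of the SSI formula; defaults are the published values.

    ``a`` scales the whole bracket, ``b`` and ``c`` set the humidity
    weighting (``c`` per percent humidity), ``pivot`` is the temperature
    (degF) at which humidity has no effect, and ``offset`` shifts the
    result onto the SSI scale.
    """

    a: float = 1.98
    b: float = 0.55
    c: float = 0.0055
    pivot: float = 58.0
    offset: float = 56.83


DEFAULT_CONSTANTS = FormulaConstants()


def convert_temperature(value, from_unit: Unit | str, to_unit: Unit | str):
    """Affine degC <-> degF conversion; identity when units are equal.

    Accepts scalars or numpy arrays.
    """
    from_unit = Unit.coerce(from_unit)
    to_unit = Unit.coerce(to_unit)
    if from_unit is to_unit:
        return value
    if from_unit is Unit.CELSIUS:
        return value * 9.0 / 5.0 + 32.0
    return (value - 32.0) * 5.0 / 9.0


def compute_ssi(ta_f, ur, constants: FormulaConstants = DEFAULT_CONSTANTS):
    """SSI (degF scale) from Fahrenheit air temperature and RH in percent.

    Vectorized: works on scalars and numpy arrays alike. Humidity outside
    [0, 100] is rejected for scalars; array callers validate upstream.
    """
    if isinstance(ur, (int, float)) and not (0.0 <= ur <= 100.0):
        raise ValidationError(f"relative humidity {ur!r} outside [0, 100]")
    if isinstance(ta_f, (int, float)) and not math.isfinite(ta_f):
        raise ValidationError(f"air temperature {ta_f!r} is not finite")
    k = constants
    return k.a * (ta_f - (k.b - k.c * ur) * (ta_f - k.pivot)) - k.offset


def compute_ssi_units(
    ta_value,
    in_unit: Unit | str,
    ur,
    out_unit: Unit | str = Unit.FAHRENHEIT,
    constants: FormulaConstants = DEFAULT_CONSTANTS,
):
    """SSI with unit handling: convert input to degF, apply the formula,
    convert the resulting index to ``out_unit`` for display.

    Classification must always use the Fahrenheit-scale value; callers
    that request Celsius output convert back before classifying.
    """
    ta_f = convert_temperature(ta_value, in_unit, Unit.FAHRENHEIT)
    ssi_f = compute_ssi(ta_f, ur, constants)
    return convert_temperature(ssi_f, Unit.FAHRENHEIT, out_unit)


@dataclass(frozen=True)
class ComfortCategory:
    """One thermal-comfort interval: ``[lower, upper)`` on the degF SSI scale."""

    code: int
    label: str
    lower: float  # -inf allowed
    upper: float  # +inf allowed
    description: str = ""
    color: str = "#888888"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"category {self.code}: lower {self.lower} not below upper {self.upper}"
            )

    def contains(self, ssi_f: float) -> bool:
        return self.lower <= ssi_f < self.upper


class LegendVariant(enum.Enum):
    TABLE1 = "table1"
    SIXCLASS = "sixclass"


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered, contiguous set of comfort categories covering the real line."""

    categories: tuple[ComfortCategory, ...]
    legend_variant: LegendVariant = LegendVariant.TABLE1

    def __post_init__(self):
        cats = sorted(self.categories, key=lambda c: c.lower)
        object.__setattr__(self, "categories", tuple(cats))
        for lo, hi in zip(cats, cats[1:]):
            if not math.isclose(lo.upper, hi.lower):
                raise ConfigurationError(
                    f"categories {lo.code} and {hi.code} do not tile: "
                    f"{lo.upper} != {hi.lower}"
                )
        if cats[0].lower != -math.inf or cats[-1].upper != math.inf:
            raise ConfigurationError("scheme must cover (-inf, +inf)")
        codes = [c.code for c in cats]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("duplicate category codes")

    @property
    def bounds(self) -> list[float]:
        """Interior breakpoints (len = n_categories - 1), ascending."""
        return [c.lower for c in self.categories[1:]]

    def by_code(self, code: int) -> ComfortCategory:
        for c in self.categories:
            if c.code == code:
                return c
        raise KeyError(code)

    def classify(self, ssi_f: float) -> ComfortCategory:
        return classify_ssi(ssi_f, self)

    def to_json(self) -> str:
        def enc(v):
            return None if math.isinf(v) else v

        payload = {
            "legend_variant": self.legend_variant.value,
            "categories": [
                {
                    "code": c.code,
                    "label": c.label,
                    "lower": enc(c.lower),
                    "upper": enc(c.upper),
                    "description": c.description,
                    "color": c.color,
                }
                for c in self.categories
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClassificationScheme":
        payload = json.loads(text)
        cats = tuple(
            ComfortCategory(
                code=int(c["code"]),
                label=c["label"],
                lower=-math.inf if c["lower"] is None else float(c["lower"]),
                upper=math.inf if c["upper"] is None else float(c["upper"]),
                description=c.get("description", ""),
                color=c.get("color", "#888888"),
            )
            for c in payload["categories"]
        )
        return cls(cats, LegendVariant(payload.get("legend_variant", "table1")))


def classify_ssi(ssi_f: float, scheme: ClassificationScheme) -> ComfortCategory:
    """Map a Fahrenheit-scale SSI value to its comfort category.

    Intervals are half-open ``[lower, upper)``; every finite value maps to
    exactly one category.
    """
    if not math.isfinite(ssi_f):
        raise ValidationError(f"cannot classify non-finite SSI value {ssi_f!r}")
    for cat in scheme.categories:
        if cat.contains(ssi_f):
            return cat
    raise AssertionError("unreachable: scheme covers the real line")


# The published interpretation table: eight intervals above 70 degF plus an
# explicit below-scale category (interpolated winter/highland pixels can
# legitimately fall below 70). The value 150 itself is assigned to the top
# category by closing its lower bound.
_TABLE1_ROWS: Sequence[tuple[int, str, float, float, str, str]] = (
    (0, "Below scale", -math.inf, 70.0, "Below the index's defined range; cool conditions.", "#2c7bb6"),
    (1, "Cold", 70.0, 77.0, "Cosy for most people, but a bit cool.", "#74b9d8"),
    (2, "Cold", 77.0, 83.0, "Ideal temperature; almost everyone feels comfortable.", "#abd9e9"),
    (3, "Comfortable", 83.0, 91.0, "Favourable for most people, feels a little warm.", "#ffffbf"),
    (4, "Warm-Hot", 91.0, 100.0, "Temperatures above normal values.", "#fdae61"),
    (5, "Sweltering", 100.0, 112.0, "Various disorders occur with prolonged exposure.", "#f46d43"),
    (6, "Extremely Hot", 112.0, 125.0, "High perceived temperatures for almost everyone; illness with prolonged exposure.", "#d73027"),
    (7, "Extremely Hot", 125.0, 150.0, "Affects vital functions of vulnerable groups (patients, elderly, children).", "#a50026"),
    (8, "Deadly Hot", 150.0, math.inf, "Fatal consequences in case of prolonged exposure.", "#67001f"),
)

# The six-label legend used for population summaries. The mapping from the
# eight intervals to the six labels is a package default (configurable via
# scheme JSON): below-scale and the first interval share "Cold".
_SIXCLASS_LABELS = {0: "Cold", 1: "Cold", 2: "Cool", 3: "Comfortable",
                    4: "Warm", 5: "Hot", 6: "So Hot", 7: "So Hot", 8: "So Hot"}


def table1_scheme() -> ClassificationScheme:
    """The standard eight-interval interpretation table (plus below-scale)."""
    return ClassificationScheme(
        tuple(ComfortCategory(*row) for row in _TABLE1_ROWS),
        LegendVariant.TABLE1,
    )


def sixclass_scheme() -> ClassificationScheme:
    """Same interval structure, relabelled with the six summary labels."""
    cats = tuple(
        ComfortCategory(code, _SIXCLASS_LABELS[code], lo, hi, desc, color)
        for code, _, lo, hi, desc, color in _TABLE1_ROWS
    )
    return ClassificationScheme(cats, LegendVariant.SIXCLASS)
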