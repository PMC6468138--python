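"""Core domain types for macronutrient-niche analysis.

The pipeline operates on three kinds of records:

* :class:`ProximateRecord` — laboratory proximate composition of one food
  (ash, crude protein, ether extract, moisture, crude fiber, available
  carbohydrate; percent of sample mass).
* :class:`MacronutrientProfile` — a food or diet expressed as percentages of
  total macronutrient-derived metabolizable energy (protein, lipid,
  carbohydrate; sums to 100).
* :class:`DietComposition` — a scat-based diet table: percent relative
  frequency (RF%) per identified food plus an unidentified remainder.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "StudyArea",
    "Season",
    "ProximateRecord",
    "MacronutrientProfile",
    "DietComposition",
    "EnergyConversion",
    "DietSummary",
    "SchemaError",
    "ValidationError",
]

#: Slack allowed when checking that tabulated percentages total 100
#: (published tables are rounded to 1–2 decimal places).
TOTAL_TOLERANCE = 0.1

MACRONUTRIENTS = ("protein", "lipid", "carbohydrate")


class SchemaError(ValueError):
    """A tabular input is missing a mandatory column or row."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, total, duplicate)."""


class StudyArea(str, enum.Enum):
    """Origin of a record: one of the two field sites, or the literature."""

    DHR = "DHR"
    KSL = "KSL"
    LITERATURE = "literature"


class Season(str, enum.Enum):
    SUMMER = "summer"
    AUTUMN = "autumn"
    ANY = "any"


@dataclass(frozen=True)
class ProximateRecord:
    """Proximate composition of one food, as percent of sample mass.

    ``available_carbohydrate_pct`` may be ``None`` when the laboratory table
    did not report it; it is then derived by difference
    (see :func:`macroniche.energetics.available_carbohydrate_by_difference`).
    """

    food_id: str
    study_area: StudyArea
    season: Season
    ash_pct: float
    crude_protein_pct: float
    ether_extract_pct: float
    moisture_pct: float
    crude_fiber_pct: float
    available_carbohydrate_pct: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for name in (
            "ash_pct",
            "crude_protein_pct",
            "ether_extract_pct",
            "moisture_pct",
            "crude_fiber_pct",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{self.food_id}: {name}={v!r} outside [0, 100]"
                )
        ac = self.available_carbohydrate_pct
        if ac is not None:
            if not 0.0 <= ac <= 100.0:
                raise ValidationError(
                    f"{self.food_id}: available_carbohydrate_pct={ac!r} "
                    "outside [0, 100]"
                )
            total = (
                self.ash_pct
                + self.crude_protein_pct
                + self.ether_extract_pct
                + self.moisture_pct
                + self.crude_fiber_pct
                + ac
            )
            if not 99.9 <= total <= 100.1:
                raise ValidationError(
                    f"{self.food_id}: proximate components total {total:.2f}, "
                    "expected 100 ± 0.1"
                )

    @property
    def has_carbohydrate(self) -> bool:
        return self.available_carbohydrate_pct is not None


@dataclass(frozen=True)
class MacronutrientProfile:
    """Protein/lipid/carbohydrate as % of macronutrient metabolizable energy.

    Components are non-negative and sum to 100 (checked to 1e-9 by
    :meth:`validate`; construction via :meth:`from_energy` or
    :meth:`renormalized` guarantees it).  Values are carried unrounded;
    rounding to display precision happens only in reports.
    """

    protein_pct: float
    lipid_pct: float
    carbohydrate_pct: float

    SUM_TOLERANCE = 1e-9

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, v in zip(MACRONUTRIENTS, self.as_tuple()):
            if v < -self.SUM_TOLERANCE:
                raise ValidationError(f"{name} component negative: {v!r}")
        total = sum(self.as_tuple())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValidationError(
                f"profile components sum to {total!r}, expected 100"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.protein_pct, self.lipid_pct, self.carbohydrate_pct)

    def component(self, name: str) -> float:
        """Component by macronutrient name or one-letter symbol (P/L/C)."""
        key = {"p": "protein", "l": "lipid", "c": "carbohydrate"}.get(
            name.lower(), name.lower()
        )
        try:
            idx = MACRONUTRIENTS.index(key)
        except ValueError:
            raise KeyError(f"unknown macronutrient {name!r}") from None
        return self.as_tuple()[idx]

    @classmethod
    def renormalized(
        cls, protein: float, lipid: float, carbohydrate: float
    ) -> "MacronutrientProfile":
        """Build a profile from non-negative parts, rescaled to sum to 100."""
        total = protein + lipid + carbohydrate
        if total <= 0:
            raise ValidationError("cannot normalize an all-zero profile")
        return cls(
            100.0 * protein / total,
            100.0 * lipid / total,
            100.0 * carbohydrate / total,
        )

    def round(self, ndigits: int = 1) -> tuple[float, float, float]:
        """Display rounding (half-up) of the three components."""
        return tuple(_round_half_up(v, ndigits) for v in self.as_tuple())

    def __format__(self, spec: str) -> str:
        p, l, c = self.round(int(spec) if spec else 1)
        return f"{p}P:{l}L:{c}C"


def _round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass
class DietComposition:
    """One study-area/season diet: RF% per identified food + unidentified.

    ``items`` maps food_id -> percent relative frequency over all fragments;
    identified items plus ``unidentified_rf_pct`` must total 100 (within
    printed-table rounding slack).  ``categories`` optionally carries the
    table's food-category labels (Bamboo, Crop, Hard mast, ...).
    """

    study_area: StudyArea
    season: Season
    items: dict[str, float]
    unidentified_rf_pct: float = 0.0
    n_scats: int | None = None
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for food, rf in self.items.items():
            if rf < 0:
                raise ValidationError(f"{food}: rf_pct={rf!r} negative")
        if self.unidentified_rf_pct < 0:
            raise ValidationError("unidentified_rf_pct negative")
        total = self.total_rf
        if abs(total - 100.0) > TOTAL_TOLERANCE:
            raise ValidationError(
                f"diet RF% totals {total:.2f}, expected 100 ± "
                f"{TOTAL_TOLERANCE}"
            )

    @property
    def identified_rf(self) -> float:
        return sum(self.items.values())

    @property
    def total_rf(self) -> float:
        return self.identified_rf + self.unidentified_rf_pct

    @property
    def label(self) -> str:
        return f"{self.study_area.value}_{self.season.value}"


@dataclass(frozen=True)
class EnergyConversion:
    """Metabolizable-energy conversion factors, kcal per gram.

    Defaults are the standard factors: 4 kcal/g for protein and
    carbohydrate, 9 kcal/g for lipid.  Override for e.g.
    digestibility-corrected factors.
    """

    protein_kcal_per_g: float = 4.0
    carbohydrate_kcal_per_g: float = 4.0
    lipid_kcal_per_g: float = 9.0

    def __post_init__(self) -> None:
        if min(
            self.protein_kcal_per_g,
            self.carbohydrate_kcal_per_g,
            self.lipid_kcal_per_g,
        ) <= 0:
            raise ValidationError("energy conversion factors must be > 0")


@dataclass(frozen=True)
class DietSummary:
    """Per-macronutrient mean / sample SD / CV over a group of diet points.

    ``mean``, ``sd`` and ``cv`` map macronutrient name -> value.  SD uses the
    n-1 (sample) denominator; CV = SD / mean.  For groups of fewer than two
    diets SD and CV are ``None`` (undefined).
    """

    group_label: str
    mean: dict[str, float]
    sd: dict[str, float] | None
    cv: dict[str, float] | None
    n_diets: int
    n_scats: int | None = None
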