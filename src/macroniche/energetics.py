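"""Proximate composition → metabolizable-energy macronutrient profiles.

Each food's crude protein (CP), ether extract (EE, crude fat) and available
carbohydrate (AC) are converted to metabolizable energy with standard
factors (protein and carbohydrate 4 kcal/g, lipid 9 kcal/g) and expressed as
percentages of total macronutrient-derived energy:

    P = 100·fp·CP / T,  L = 100·fl·EE / T,  C = 100·fc·AC / T,
    T = fp·CP + fl·EE + fc·AC

Crude fiber, ash and moisture contribute no macronutrient energy: fiber is
excluded from AC by the by-difference estimate, and only CP/EE/AC enter the
conversion.  The resulting profile is scale-invariant in (CP, EE, AC).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

from .io import bundled_insect_profiles, bundled_proximate_records
from .types import (
    EnergyConversion,
    MacronutrientProfile,
    ProximateRecord,
    ValidationError,
)

__all__ = [
    "available_carbohydrate_by_difference",
    "macronutrient_profile",
    "profile_table",
    "bundled_food_profiles",
]

#: Components do not total >100 beyond this slack (rounded published rows).
_MASS_SLACK = 0.1


def available_carbohydrate_by_difference(record: ProximateRecord) -> float:
    """Estimate available carbohydrate (% of mass) by subtraction.

    AC = 100 − ash − CP − EE − moisture − CF, floored at zero when the
    rounded components overshoot 100 by at most 0.1.

    Raises
    ------
    ValidationError
        If the five components total more than 100.1 (a genuinely negative
        AC, beyond rounding slack).
    """
    other = (
        record.ash_pct
        + record.crude_protein_pct
        + record.ether_extract_pct
        + record.moisture_pct
        + record.crude_fiber_pct
    )
    if other > 100.0 + _MASS_SLACK:
        raise ValidationError(
            f"{record.food_id}: non-carbohydrate components total "
            f"{other:.2f} > 100.1; cannot estimate AC by difference"
        )
    return max(0.0, 100.0 - other)


def macronutrient_profile(
    record: ProximateRecord,
    conv: EnergyConversion = EnergyConversion(),
) -> MacronutrientProfile:
    """Convert one proximate record to an energy-proportion profile.

    Uses the record's tabulated available carbohydrate when present, else
    derives it by difference.

    Raises
    ------
    ValidationError
        If CP, EE and AC are all zero (total macronutrient energy is zero,
        the profile is undefined).
    """
    cp = record.crude_protein_pct
    ee = record.ether_extract_pct
    ac = (
        record.available_carbohydrate_pct
        if record.has_carbohydrate
        else available_carbohydrate_by_difference(record)
    )
    p_kcal = conv.protein_kcal_per_g * cp
    l_kcal = conv.lipid_kcal_per_g * ee
    c_kcal = conv.carbohydrate_kcal_per_g * ac
    total = p_kcal + l_kcal + c_kcal
    if total <= 0:
        raise ValidationError(
            f"{record.food_id}: zero macronutrient energy, profile undefined"
        )
    return MacronutrientProfile(
        100.0 * p_kcal / total,
        100.0 * l_kcal / total,
        100.0 * c_kcal / total,
    )


def profile_table(
    records: Iterable[ProximateRecord],
    insects: Mapping[str, MacronutrientProfile] | None = None,
    conv: EnergyConversion = EnergyConversion(),
) -> dict[str, MacronutrientProfile]:
    """Convert a set of proximate records and merge pass-through profiles.

    ``insects`` (or any pre-computed energy-proportion profiles, e.g.
    literature constants) are included unchanged.

    Raises
    ------
    ValidationError
        On duplicate food_ids, within the records or against ``insects``.
    """
    table: dict[str, MacronutrientProfile] = {}
    for record in records:
        if record.food_id in table:
            raise ValidationError(f"duplicate food_id {record.food_id!r}")
        table[record.food_id] = macronutrient_profile(record, conv)
    for food_id, profile in (insects or {}).items():
        if food_id in table:
            raise ValidationError(f"duplicate food_id {food_id!r}")
        table[food_id] = profile
    return table


def bundled_food_profiles(
    name: str, conv: EnergyConversion = EnergyConversion()
) -> dict[str, MacronutrientProfile]:
    """Energy-proportion profiles for every food in a bundled diet.

    Assembles the study-area/season proximate records, the literature insect
    constants (consumed only in the DHR), and one substitution: the DHR
    summer diet contains fern but the DHR summer composite samples do not,
    so the KSL summer fern record stands in for it (flagged in the record's
    ``note``).
    """
    from .io import _check_fixture  # fixture-name validation

    key = _check_fixture(name)
    records = list(bundled_proximate_records(key))
    if key == "dhr_summer":
        ksl = {r.food_id: r for r in bundled_proximate_records("ksl_summer")}
        fern = ksl["Fern"]
        records.append(
            ProximateRecord(
                food_id=fern.food_id,
                study_area=fern.study_area,
                season=fern.season,
                ash_pct=fern.ash_pct,
                crude_protein_pct=fern.crude_protein_pct,
                ether_extract_pct=fern.ether_extract_pct,
                moisture_pct=fern.moisture_pct,
                crude_fiber_pct=fern.crude_fiber_pct,
                available_carbohydrate_pct=fern.available_carbohydrate_pct,
                note="substituted from KSL summer composite",
            )
        )
    insects = bundled_insect_profiles() if key.startswith("dhr") else None
    return profile_table(records, insects, conv)
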