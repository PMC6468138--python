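"""Tabular readers/writers and the bundled Nepal black-bear dataset.

Two delimited-text schemas (comma-separated, UTF-8, ``.`` decimal):

**Proximate tables** — one row per food, columns ``food_id``, ``study_area``,
``season``, ``ash_pct``, ``crude_protein_pct``, ``ether_extract_pct``,
``moisture_pct``, ``crude_fiber_pct``, ``available_carbohydrate_pct``
(optional — may be blank, derived by difference downstream), plus optional
``species`` and ``note`` columns.

**Diet tables** — one row per food with columns ``food_id``, ``category``,
``rf_pct`` (percent relative frequency), one ``Unidentified`` row, and
``# key: value`` comment lines carrying study area, season and scat count.

The bundled dataset covers two study areas (Dhorpatan Hunting Reserve, DHR;
Kailash Sacred Landscape, KSL) and two seasons, addressable by fixture names
``dhr_summer``, ``dhr_autumn``, ``ksl_summer``, ``ksl_autumn``.  Literature
energy-proportion constants for ants and termites are provided by
:func:`bundled_insect_profiles`; they are stored as profiles, not proximate
rows, because the source reports them already in energy-proportion form.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import (
    DietComposition,
    MacronutrientProfile,
    ProximateRecord,
    SchemaError,
    Season,
    StudyArea,
    ValidationError,
)

__all__ = [
    "read_proximate_table",
    "write_proximate_table",
    "read_diet_table",
    "write_diet_table",
    "bundled_insect_profiles",
    "bundled_proximate_records",
    "bundled_diet",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("dhr_summer", "dhr_autumn", "ksl_summer", "ksl_autumn")

_PROXIMATE_COLUMNS = (
    "food_id",
    "study_area",
    "season",
    "ash_pct",
    "crude_protein_pct",
    "ether_extract_pct",
    "moisture_pct",
    "crude_fiber_pct",
)
_DIET_COLUMNS = ("food_id", "rf_pct")

#: RF% row label for unidentified scat fragments.
UNIDENTIFIED = "Unidentified"


def read_proximate_table(path: str | Path | _io.TextIOBase) -> list[ProximateRecord]:
    """Read a proximate-composition table into :class:`ProximateRecord` rows.

    ``available_carbohydrate_pct`` may be absent (column missing or blank);
    such records are flagged via ``record.has_carbohydrate``.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    ValidationError
        If a value is negative, out of range, or components do not total 100.
    """
    df = pd.read_csv(path, comment="#", dtype={"food_id": str})
    missing = [c for c in _PROXIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"proximate table missing column(s): {', '.join(missing)}")
    has_ac = "available_carbohydrate_pct" in df.columns
    records = []
    for i, row in df.iterrows():
        ac = row["available_carbohydrate_pct"] if has_ac else None
        if ac is not None and pd.isna(ac):
            ac = None
        try:
            records.append(
                ProximateRecord(
                    food_id=row["food_id"],
                    study_area=StudyArea(row["study_area"]),
                    season=Season(row["season"]),
                    ash_pct=float(row["ash_pct"]),
                    crude_protein_pct=float(row["crude_protein_pct"]),
                    ether_extract_pct=float(row["ether_extract_pct"]),
                    moisture_pct=float(row["moisture_pct"]),
                    crude_fiber_pct=float(row["crude_fiber_pct"]),
                    available_carbohydrate_pct=None if ac is None else float(ac),
                    note="" if "note" not in df.columns or pd.isna(row.get("note")) else str(row["note"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_proximate_table(records: list[ProximateRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "food_id": [r.food_id for r in records],
            "study_area": [r.study_area.value for r in records],
            "season": [r.season.value for r in records],
            "ash_pct": [r.ash_pct for r in records],
            "crude_protein_pct": [r.crude_protein_pct for r in records],
            "ether_extract_pct": [r.ether_extract_pct for r in records],
            "moisture_pct": [r.moisture_pct for r in records],
            "crude_fiber_pct": [r.crude_fiber_pct for r in records],
            "available_carbohydrate_pct": [
                r.available_carbohydrate_pct for r in records
            ],
            "note": [r.note for r in records],
        }
    )
    df.to_csv(path, index=False)


def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_diet_table(
    path: str | Path | _io.TextIOBase,
    *,
    study_area: StudyArea | str | None = None,
    season: Season | str | None = None,
    n_scats: int | None = None,
) -> DietComposition:
    """Read an RF% diet table into a :class:`DietComposition`.

    The ``Unidentified`` row is mandatory and stored separately from the
    identified items.  Study area, season and scat count are read from
    ``# key: value`` header comments unless given as keyword arguments.

    Raises
    ------
    SchemaError
        Missing columns or missing ``Unidentified`` row.
    ValidationError
        Identified + unidentified RF% totals outside 100 ± 0.1.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    meta = _parse_metadata(lines)
    df = pd.read_csv(_io.StringIO(text), comment="#", dtype={"food_id": str})
    missing = [c for c in _DIET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"diet table missing column(s): {', '.join(missing)}")

    mask = df["food_id"].str.strip().str.lower() == UNIDENTIFIED.lower()
    if not mask.any():
        raise SchemaError(f"diet table has no {UNIDENTIFIED!r} row")
    unidentified = float(df.loc[mask, "rf_pct"].sum())
    identified = df.loc[~mask]
    items = dict(zip(identified["food_id"], identified["rf_pct"].astype(float)))
    if len(items) != len(identified):
        raise ValidationError("duplicate food_id in diet table")

    categories = {}
    if "category" in df.columns:
        for _, row in identified.iterrows():
            if not pd.isna(row["category"]):
                categories[row["food_id"]] = str(row["category"])

    area = study_area if study_area is not None else meta.get("study_area")
    seas = season if season is not None else meta.get("season")
    if area is None or seas is None:
        raise SchemaError(
            "study_area/season not found in header comments nor arguments"
        )
    if n_scats is None and "n_scats" in meta:
        n_scats = int(meta["n_scats"])
    return DietComposition(
        study_area=StudyArea(area),
        season=Season(seas),
        items=items,
        unidentified_rf_pct=unidentified,
        n_scats=n_scats,
        categories=categories,
    )


def write_diet_table(diet: DietComposition, path: str | Path) -> None:
    """Write a diet table in the same schema ``read_diet_table`` accepts.

    RF% values round-trip at 1-decimal precision (the precision of the
    source tables).
    """
    out = [
        f"# study_area: {diet.study_area.value}",
        f"# season: {diet.season.value}",
    ]
    if diet.n_scats is not None:
        out.append(f"# n_scats: {diet.n_scats}")
    out.append("food_id,category,rf_pct")
    for food, rf in diet.items.items():
        cat = diet.categories.get(food, "")
        out.append(f"{food},{cat},{rf:g}")
    out.append(f"{UNIDENTIFIED},,{diet.unidentified_rf_pct:g}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def bundled_insect_profiles() -> dict[str, MacronutrientProfile]:
    """Literature macronutrient-energy profiles for ants and termites.

    The published triplets (ants 37.7P:45.8L:16.4C, termites
    26.8P:55.9L:17.3C) are rounded to 1 dp and total 99.9–100.0; each is
    renormalized here so components sum to exactly 100.
    """
    return {
        "Ants": MacronutrientProfile.renormalized(37.7, 45.8, 16.4),
        "Termites": MacronutrientProfile.renormalized(26.8, 55.9, 17.3),
    }


def _data_path(filename: str):
    return resources.files("macroniche.data").joinpath(filename)


def _check_fixture(name: str) -> str:
    key = name.lower()
    if key not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return key


def bundled_proximate_records(name: str) -> list[ProximateRecord]:
    """Proximate-composition records for one bundled study-area/season.

    Note: the DHR summer table has no fern row; the DHR summer *diet*
    includes fern, which the bundled profile assembly substitutes from the
    KSL summer fern composite (see
    :func:`macroniche.energetics.bundled_food_profiles`).
    """
    key = _check_fixture(name)
    with resources.as_file(_data_path(f"{key}_proximate.csv")) as p:
        return read_proximate_table(p)


def bundled_diet(name: str) -> DietComposition:
    """RF% diet composition for one bundled study-area/season."""
    key = _check_fixture(name)
    with resources.as_file(_data_path(f"{key}_diet.csv")) as p:
        return read_diet_table(p)
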