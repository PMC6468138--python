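"""Synthetic proximate and diet tables with known ground truth.

Food profiles are drawn from a Dirichlet law on the (P, L, C) simplex and
RF% weights from a symmetric Dirichlet, so every downstream stage —
energy conversion, renormalized mixing, hull geometry — can be checked
against the exact generating truth.  Emitted tables use the same delimited
schemas as :mod:`macroniche.io` and respect the same invariants (RF%
rounded to 1 dp with largest-remainder repair so totals hit 100; proximate
rows whose conversion recovers the generating profile exactly).

The defaults mimic the bundled field data: carbohydrate-dominated food
profiles with moderate spread (Dirichlet α = (2, 1, 5)), and a 5%
unidentified fraction, inside the 1.6–5.4% range of the bundled diet
tables.  What the generator does *not* emulate: microhistological fragment
counting (RF% is drawn directly, not from per-scat multinomials), and any
correlation between a food's RF% and its composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as mio
from .energetics import macronutrient_profile
from .mixing import mix_diet
from .rmt import NicheHull, food_hull
from .types import (
    DietComposition,
    EnergyConversion,
    MacronutrientProfile,
    ProximateRecord,
    Season,
    StudyArea,
    ValidationError,
)

__all__ = [
    "SyntheticScenario",
    "gen_food_profiles",
    "gen_diet_table",
    "gen_proximate_from_profile",
    "make_scenario",
    "write_scenario",
]

DEFAULT_PROFILE_CONCENTRATION = (2.0, 1.0, 5.0)
DEFAULT_WEIGHT_CONCENTRATION = 2.0
DEFAULT_UNIDENTIFIED_FRAC = 0.05


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_food_profiles(
    n: int,
    concentration=DEFAULT_PROFILE_CONCENTRATION,
    seed=None,
) -> list[MacronutrientProfile]:
    """Draw ``n`` macronutrient profiles from Dirichlet(concentration)·100.

    ``concentration`` is the (P, L, C) concentration triple; large values
    concentrate profiles near the mean composition, small values spread
    them toward the simplex corners.
    """
    if n < 1:
        raise ValidationError("need n >= 1 profiles")
    alpha = np.asarray(concentration, dtype=float)
    if alpha.shape != (3,) or np.any(alpha <= 0):
        raise ValidationError(
            f"concentration must be a positive triple, got {concentration!r}"
        )
    draws = _rng(seed).dirichlet(alpha, size=n) * 100.0
    return [MacronutrientProfile.renormalized(*row) for row in draws]


def _largest_remainder_tenths(values: np.ndarray) -> np.ndarray:
    """Round percentages to 1 dp so they still total exactly 100.0."""
    tenths = values * 10.0
    floored = np.floor(tenths)
    deficit = int(round(1000 - floored.sum()))
    order = np.argsort(-(tenths - floored), kind="stable")
    floored[order[:deficit]] += 1
    return floored / 10.0


def gen_diet_table(
    profiles: list[MacronutrientProfile],
    weight_concentration: float = DEFAULT_WEIGHT_CONCENTRATION,
    unidentified_frac: float = DEFAULT_UNIDENTIFIED_FRAC,
    seed=None,
    study_area: StudyArea = StudyArea.DHR,
    season: Season = Season.SUMMER,
) -> tuple[DietComposition, MacronutrientProfile]:
    """Generate an RF% diet table over ``profiles`` plus its truth point.

    True weights w ~ Dirichlet(weight_concentration · 1); RF% is
    w·(100 − unidentified) rounded to 1 dp with largest-remainder repair so
    the printed table totals exactly 100.  The returned truth point is the
    *unrounded* w-mixture of the profiles; the table's recomputed diet
    point differs from it only by the RF rounding.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    if not 0.0 <= unidentified_frac <= 0.2:
        raise ValidationError("unidentified_frac must lie in [0, 0.2]")
    rng = _rng(seed)
    n = len(profiles)
    weights = rng.dirichlet(np.full(n, float(weight_concentration)))
    truth = MacronutrientProfile(
        *(
            float(np.dot(weights, [p.as_tuple()[i] for p in profiles]))
            for i in range(3)
        )
    )
    raw = np.append(weights * (100.0 - 100.0 * unidentified_frac),
                    100.0 * unidentified_frac)
    rounded = _largest_remainder_tenths(raw)
    items = {f"food_{i + 1:02d}": float(rounded[i]) for i in range(n)}
    diet = DietComposition(
        study_area=study_area,
        season=season,
        items=items,
        unidentified_rf_pct=float(rounded[-1]),
    )
    return diet, truth


def gen_proximate_from_profile(
    profile: MacronutrientProfile,
    moisture: float = 10.0,
    ash: float = 8.0,
    fiber: float = 25.0,
    dry_mass_scale: float = 1.0,
    seed=None,
    food_id: str = "synthetic",
    study_area: StudyArea = StudyArea.DHR,
    season: Season = Season.SUMMER,
    conv: EnergyConversion = EnergyConversion(),
) -> ProximateRecord:
    """Invert the energy conversion: build a proximate row for a profile.

    Macronutrient masses are proportional to (P/fp, L/fl, C/fc), scaled to
    ``dry_mass_scale`` of the mass left after moisture, ash and fiber (the
    un-scaled remainder is added to crude fiber, exploiting the conversion's
    scale invariance).  If ``seed`` is given, moisture/ash/fiber are each
    jittered by ±25% first.  ``macronutrient_profile`` of the result
    recovers ``profile`` to floating-point precision.
    """
    rng = _rng(seed) if seed is not None else None
    if rng is not None:
        moisture, ash, fiber = (
            v * rng.uniform(0.75, 1.25) for v in (moisture, ash, fiber)
        )
    if not 0.0 < dry_mass_scale <= 1.0:
        raise ValidationError("dry_mass_scale must lie in (0, 1]")
    budget = 100.0 - moisture - ash - fiber
    if budget <= 0:
        raise ValidationError(
            f"moisture + ash + fiber = {moisture + ash + fiber:.2f} "
            "leaves no mass for macronutrients"
        )
    p, l, c = profile.as_tuple()
    raw = np.array(
        [p / conv.protein_kcal_per_g, l / conv.lipid_kcal_per_g,
         c / conv.carbohydrate_kcal_per_g]
    )
    masses = raw / raw.sum() * budget * dry_mass_scale
    fiber = fiber + budget * (1.0 - dry_mass_scale)
    return ProximateRecord(
        food_id=food_id,
        study_area=study_area,
        season=season,
        ash_pct=ash,
        crude_protein_pct=float(masses[0]),
        ether_extract_pct=float(masses[1]),
        moisture_pct=moisture,
        crude_fiber_pct=fiber,
        available_carbohydrate_pct=float(masses[2]),
        note="synthetic",
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """One generated dataset plus its exact generating truth.

    Regeneration from the same seed is bit-identical.  The truth diet point
    is the convex combination of the truth profiles under the truth weights
    (before RF rounding); ``truth_hull`` is the niche hull of the truth
    profiles under the default axes.
    """

    seed: int
    n_foods: int
    profile_concentration: tuple[float, float, float]
    weight_concentration: float
    unidentified_frac: float
    profiles: dict[str, MacronutrientProfile]
    records: tuple[ProximateRecord, ...]
    diet: DietComposition
    truth_point: MacronutrientProfile
    truth_hull: NicheHull


def make_scenario(
    seed: int,
    n_foods: int = 8,
    profile_concentration=DEFAULT_PROFILE_CONCENTRATION,
    weight_concentration: float = DEFAULT_WEIGHT_CONCENTRATION,
    unidentified_frac: float = DEFAULT_UNIDENTIFIED_FRAC,
    study_area: StudyArea = StudyArea.DHR,
    season: Season = Season.SUMMER,
) -> SyntheticScenario:
    """Generate a full scenario: profiles, proximate rows, diet table, truth."""
    rng = np.random.default_rng(seed)
    profiles = gen_food_profiles(n_foods, profile_concentration, rng)
    diet, truth = gen_diet_table(
        profiles,
        weight_concentration,
        unidentified_frac,
        rng,
        study_area=study_area,
        season=season,
    )
    named = dict(zip(diet.items.keys(), profiles))
    records = tuple(
        gen_proximate_from_profile(
            prof,
            seed=rng,
            food_id=food,
            study_area=study_area,
            season=season,
        )
        for food, prof in named.items()
    )
    return SyntheticScenario(
        seed=seed,
        n_foods=n_foods,
        profile_concentration=tuple(profile_concentration),
        weight_concentration=weight_concentration,
        unidentified_frac=unidentified_frac,
        profiles=named,
        records=records,
        diet=diet,
        truth_point=truth,
        truth_hull=food_hull(profiles, label=f"synthetic_{seed}"),
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario's proximate and diet tables in the standard schemas.

    The files flow through :func:`macroniche.io.read_proximate_table` /
    :func:`~macroniche.io.read_diet_table` (and hence the CLI) unchanged.
    Returns the written paths keyed by table kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppath = outdir / "synthetic_proximate.csv"
    dpath = outdir / "synthetic_diet.csv"
    mio.write_proximate_table(list(scenario.records), ppath)
    mio.write_diet_table(scenario.diet, dpath)
    return {"proximate": ppath, "diet": dpath}
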