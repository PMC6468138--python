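"""RF%-weighted diet mixing and group summaries.

A diet's realized macronutrient niche is the convex combination of its
foods' energy-proportion profiles, weighted by percent relative frequency
(RF%) renormalized over identified items — i.e. unidentified material is
removed and the remaining weights rescaled to sum to one before mixing.

Group means (seasonal, study-area, overall) are unweighted means of the
member diet points; scat counts travel as metadata only.  Spread statistics
use the sample (n−1) standard deviation and CV = SD/mean, computed from
unrounded diet points.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence

from .types import (
    MACRONUTRIENTS,
    DietComposition,
    DietSummary,
    MacronutrientProfile,
    ValidationError,
)

__all__ = [
    "renormalized_weights",
    "mix_diet",
    "pooled_diet",
    "summarize_group",
    "category_rf_sum",
]


def renormalized_weights(diet: DietComposition) -> dict[str, float]:
    """Mixing weights: RF% renormalized over identified items.

    weight_i = rf_i / Σ identified rf; weights sum to 1.  This is the
    correction for unidentified material.

    Raises
    ------
    ValidationError
        If the diet has no identified material (all unidentified).
    """
    total = diet.identified_rf
    if total <= 0:
        raise ValidationError(
            f"{diet.label}: no identified RF%, weights undefined"
        )
    return {food: rf / total for food, rf in diet.items.items()}


def mix_diet(
    diet: DietComposition,
    profiles: Mapping[str, MacronutrientProfile],
) -> MacronutrientProfile:
    """Realized-niche diet point: weighted mean of food profiles.

    Raises
    ------
    KeyError
        If an identified food has no profile (names the food).
    """
    weights = renormalized_weights(diet)
    missing = [f for f in weights if f not in profiles]
    if missing:
        raise KeyError(
            f"{diet.label}: no macronutrient profile for "
            f"{', '.join(sorted(missing))}"
        )
    parts = [0.0, 0.0, 0.0]
    for food, w in weights.items():
        for i, v in enumerate(profiles[food].as_tuple()):
            parts[i] += w * v
    return MacronutrientProfile(*parts)


def pooled_diet(diets: Sequence[MacronutrientProfile]) -> MacronutrientProfile:
    """Unweighted component-wise mean of diet points.

    Each subpopulation/season diet counts equally regardless of how many
    scats produced it; scat counts are metadata, not weights.
    """
    if not diets:
        raise ValidationError("pooled_diet of an empty list is undefined")
    n = len(diets)
    return MacronutrientProfile(
        *(sum(d.as_tuple()[i] for d in diets) / n for i in range(3))
    )


def summarize_group(
    diets: Sequence[MacronutrientProfile],
    label: str,
    n_scats: int | None = None,
) -> DietSummary:
    """Per-macronutrient mean, sample SD and CV over a group of diet points.

    SD uses the n−1 denominator; CV = SD/mean.  With fewer than two diets
    SD and CV are reported as undefined (``None``).  Statistics are computed
    from the unrounded diet points.
    """
    if not diets:
        raise ValidationError("cannot summarize an empty group")
    n = len(diets)
    mean = {
        m: sum(d.component(m) for d in diets) / n for m in MACRONUTRIENTS
    }
    if n < 2:
        return DietSummary(label, mean, None, None, n, n_scats)
    sd = {
        m: math.sqrt(
            sum((d.component(m) - mean[m]) ** 2 for d in diets) / (n - 1)
        )
        for m in MACRONUTRIENTS
    }
    cv = {m: (sd[m] / mean[m] if mean[m] > 0 else float("nan")) for m in MACRONUTRIENTS}
    return DietSummary(label, mean, sd, cv, n, n_scats)


def category_rf_sum(
    diet: DietComposition,
    category: str,
    category_map: Mapping[str, str] | None = None,
) -> float:
    """Total *uncorrected* RF% of a food category (e.g. ``"Crop"``).

    Sums raw RF% over foods assigned to ``category`` — no renormalization
    for unidentified material, matching how category totals are read
    straight off a diet table.  ``category_map`` defaults to the categories
    carried by the diet table itself.

    Raises
    ------
    KeyError
        If the category is not present in the category map at all.
    """
    cmap = category_map if category_map is not None else diet.categories
    if category not in set(cmap.values()):
        raise KeyError(f"unknown category {category!r}")
    return sum(
        rf for food, rf in diet.items.items() if cmap.get(food) == category
    )
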