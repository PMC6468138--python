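# Methods

## Model and assumptions

A food is represented by its proximate composition, the standard
feed-chemistry partition of sample mass into ash, crude protein (CP,
Kjeldahl nitrogen × factor), ether extract (EE, crude fat), moisture, crude
fiber (CF) and available carbohydrate (AC). When AC is not assayed it is
estimated by difference, AC = 100 − ash − CP − EE − moisture − CF, floored
at zero (the published tables are rounded, so sums can overshoot 100 by up
to 0.1; a larger overshoot is treated as a data error).

Macronutrient energy uses the standard metabolizable-energy factors — 4
kcal/g for protein and carbohydrate, 9 kcal/g for lipid — applied to CP, EE
and AC. The factors are configurable (`EnergyConversion`) because some
studies prefer digestibility-corrected values; crude fiber, ash and
moisture contribute no macronutrient energy. The tabulated proximate values
are used as-is (no dry-matter re-basis): moisture is carried through the
types but does not enter the conversion. A food's **profile** is then each
macronutrient's share of total macronutrient energy; profiles are
compositions summing to 100 and are invariant to rescaling (CP, EE, AC)
jointly, so the wet/dry basis question does not affect them.

A **diet** is a percent-relative-frequency (RF%) table over identified scat
fragments plus an unidentified remainder. The realized-niche **diet point**
is the RF-weighted mean of the food profiles after renormalizing weights
over identified items only — i.e. unidentified material is assumed to have,
on average, the macronutrient composition of the identified diet. RF% is
used as the mixing weight without any digestibility (fecal-correction)
adjustment; none is applied anywhere in the pipeline.

Group summaries (per season, per study area, overall) are *unweighted*
means of member diet points: each subpopulation-season diet counts once,
and scat counts are carried as metadata only. Spread uses the sample (n−1)
standard deviation and CV = SD/mean, computed from unrounded diet points;
rounding to display precision (1 dp for percentages, 2 dp for CV) happens
only in reports, because two-decimal published spreads only reproduce from
unrounded intermediates.

## Niche geometry

Profiles are projected into a right-angled mixture triangle: two
macronutrients as explicit x/y axes, the third implicit as 100 − x − y. The
default axes are x = carbohydrate, y = protein (lipid implicit), chosen
because the bundled diets are carbohydrate-dominated; the choice is
cosmetic, since all profile points lie on the plane P + L + C = 100 and
each coordinate projection of that plane scales areas by the same factor —
hull areas and therefore breadth ratios are provably axis-invariant (and
asserted so in tests).

Niche breadth is the convex-hull area of a group's *food* points (the diet
point is plotted but never a hull input, and the unidentified category has
no point). The hull uses Andrew's monotone chain — deterministic output,
counter-clockwise from the lexicographic minimum, collinear edge points
dropped, so the vertex list is the minimal extreme set — and areas use the
shoelace formula. Fewer than three distinct non-collinear points give a
degenerate hull with area 0 and a flag rather than an error; breadth
*ratios* (max/min area, with the larger group identified) require strictly
positive areas. An independent implementation (scipy's Qhull wrapper) and a
brute-force extremality oracle serve as cross-checks in the test suite
only.

## Bundled dataset notes

The bundled tables are the two-study-area (DHR, KSL), two-season Nepal
Asiatic black bear dataset: per-food proximate composites, RF% diet tables
(41/32/77/59 scats), and literature energy profiles for ants
(37.7P:45.8L:16.4C) and termites (26.8P:55.9L:17.3C), renormalized from
their printed 99.9–100.0 totals to sum exactly to 100. The DHR summer diet
contains fern with no matching DHR summer composite; the KSL summer fern
record substitutes for it, flagged in the record's `note`. This
substitution reproduces the published DHR summer diet point exactly, which
is the evidence it matches the original analysis.

## Synthetic data

The generator draws food profiles from a Dirichlet law on the (P, L, C)
simplex and RF weights from a symmetric Dirichlet, then emits tables in the
same schemas as the bundled data. Defaults, chosen to mimic the field
data: profile concentration α = (2, 1, 5) (carbohydrate-dominated foods
with realistic spread; mean profile 25P:12.5L:62.5C), weight concentration
2 (a few dominant foods, as bamboo is in the real tables), unidentified
fraction 0.05 (the real tables span 1.6–5.4%), eight foods.

RF% values are rounded to 1 dp with largest-remainder repair so synthetic
tables satisfy the same "totals 100" invariant as real ones; the stored
truth diet point is the unrounded mixture, and the rounding perturbs the
recomputed point by well under 0.15 per component (the bound asserted over
200 seeds). Proximate rows are generated by inverting the energy map — CP,
EE, AC proportional to (P/4, L/9, C/4), scaled into the mass left after
moisture/ash/fiber — so conversion recovers the generating profile to
float precision. `dry_mass_scale` assigns only a fraction of that mass to
macronutrients, adding the remainder to crude fiber (profiles are
unchanged by scale invariance); a seed jitters moisture/ash/fiber by ±25%.
The generator does **not** simulate microhistological fragment counting
(no per-scat multinomial sampling) nor any RF-composition correlation, so
passing recovery tests validates the arithmetic of the pipeline, not
field-sampling error.

The breadth-direction sanity check compares the default concentration
against a 4×-concentrated group: over 200 seeds the broader group's hull
is larger in 99% of draws.

## Numerical and comparison choices

- Profiles and diet points are carried unrounded end to end; display
  rounding is half-up.
- Reproduction checks compare to published values at ±0.1 for percentages
  and ratios (printed at 1 dp), and for SD/CV at half a unit in the last
  published digit floored at ±0.02 — e.g. the exact summer protein SD
  5.2778 matches the published "5.3" at display precision, while
  two-decimal spreads (2.14, 1.31) are held to ±0.02. The crop-category
  RF% totals are integer sums of table entries and are compared exactly.
- Geometry tolerances: 1e-9 for collinearity/containment predicates on
  percent-scale coordinates.
- Degenerate inputs: zero macronutrient energy → error; all-unidentified
  diet → error; empty group → error; <2 diets → SD/CV undefined (`None`).

## Limitations

- RF% is a fragment-frequency proxy for intake; without fecal correction
  factors the diet points inherit its biases.
- Hull area measures the spread of food compositions consumed, not intake
  variance; a rarely eaten extreme food inflates breadth as much as a
  staple.
- The pooled and group means treat each subpopulation-season as one
  observation; with two members per group the SD/CV are two-point
  statistics and should be read as descriptive only.
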