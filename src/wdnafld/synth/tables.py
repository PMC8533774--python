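"""Worked-example validation of the study's printed metadata tables.

The diet-composition and patient-cohort tables serve as small arithmetic
fixtures: the validator recomputes their totals and macronutrient energy
percentages from the ingredient rows, without deciding the internally
inconsistent entries (the printed carbohydrate energy percentage disagrees
with its own mass column, and the cohort is described as four groups while
five fibrosis stages F0-F4 are listed) - only the protein and fat checks
and the plain group sum are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

#: ingredient composition of the obesogenic Western-style diet
#: (ingredient, grams, kcal, mass percent)
WESTERN_DIET_ROWS = (
    ("Casein, 80 mesh", 200.0, 800.0, 22.12),
    ("l-cystine", 3.0, 12.0, 0.33),
    ("Maltodextrin 10", 100.0, 400.0, 11.06),
    ("Fructose", 200.0, 800.0, 22.12),
    ("Sucrose", 96.0, 384.0, 10.62),
    ("Cellulose, BW200", 50.0, 0.0, 5.53),
    ("Soybean oil", 25.0, 225.0, 2.77),
    ("Primex shortening", 135.0, 1215.0, 14.93),
    ("Lard", 20.0, 180.0, 2.21),
    ("Mineral Mix S10026", 10.0, 0.0, 1.11),
    ("Dicalcium phosphate", 13.0, 0.0, 1.44),
    ("Calcium carbonate", 5.5, 0.0, 0.61),
    ("Potassium citrate, 1 H2O", 16.5, 0.0, 1.83),
    ("Vitamin Mix V10001", 10.0, 40.0, 1.11),
    ("Choline bitartrate", 2.0, 0.0, 0.22),
    ("Cholesterol", 18.0, 0.0, 1.99),
    ("FD&C Yellow dye", 0.05, 0.0, 0.006),
)

_PROTEIN_INGREDIENTS = frozenset({"Casein, 80 mesh", "l-cystine"})
_FAT_INGREDIENTS = frozenset({"Soybean oil", "Primex shortening", "Lard"})

#: NAFLD patient cohort by fibrosis stage
VIENNA_COHORT_GROUPS = (("F0", 7), ("F1", 10), ("F2", 7), ("F3", 9), ("F4", 6))


@dataclass
class DietTable:
    rows: tuple  # (ingredient, grams, kcal, pct)

    def __post_init__(self) -> None:
        for name, grams, kcal, _ in self.rows:
            if grams < 0 or kcal < 0:
                raise ValueError(f"negative entry in diet row {name!r}")


@dataclass
class CohortTable:
    groups: tuple  # (label, n)

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if n < 0:
                raise ValueError(f"negative group size for {label!r}")


def western_diet_table() -> DietTable:
    return DietTable(WESTERN_DIET_ROWS)


def vienna_cohort_table() -> CohortTable:
    return CohortTable(VIENNA_COHORT_GROUPS)


@dataclass
class ValidationReport:
    total_grams: float
    total_kcal: float
    protein_kcal_pct: int
    fat_kcal_pct: int
    cohort_total: int


def validate_study_tables(diet: DietTable | None = None, cohort: CohortTable | None = None) -> ValidationReport:
    """Recompute table totals and macronutrient energy percentages.

    Protein energy = casein + l-cystine; fat energy = soybean oil +
    Primex shortening + lard; percentages are of total kcal, rounded to
    the nearest integer.
    """
    diet = diet if diet is not None else western_diet_table()
    cohort = cohort if cohort is not None else vienna_cohort_table()
    total_grams = sum(r[1] for r in diet.rows)
    total_kcal = sum(r[2] for r in diet.rows)
    if total_kcal <= 0:
        raise ValueError("diet table has no energy content")
    protein_kcal = sum(r[2] for r in diet.rows if r[0] in _PROTEIN_INGREDIENTS)
    fat_kcal = sum(r[2] for r in diet.rows if r[0] in _FAT_INGREDIENTS)
    return ValidationReport(
        total_grams=total_grams,
        total_kcal=total_kcal,
        protein_kcal_pct=round(100.0 * protein_kcal / total_kcal),
        fat_kcal_pct=round(100.0 * fat_kcal / total_kcal),
        cohort_total=sum(n for _, n in cohort.groups),
    )


def tumor_incidence(n_with_tumors: int = 16, n_total: int = 27) -> float:
    """Tumor incidence as a percentage, rounded to the nearest integer."""
    if n_total <= 0 or n_with_tumors < 0 or n_with_tumors > n_total:
        raise ValueError("invalid tumor counts")
    return round(100.0 * n_with_tumors / n_total)
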