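"""qNRF1.10.2 nutrient profiling and nutritional functional units.

The quality nutrient-rich food score extends the NRF family with a
protein-quality correction: per 100 g of food,

    qNRF1.10.2 = 100 * [ min(cap, protein*DIAAS/DRI_p)
                         + sum_i min(cap, nutrient_i/DRI_i)
                         - sum_j L_j/MRI_j ]

with ten encouraged nutrients i (fiber, vitamins A, B9, B12, E, D, Zn,
Mg, Ca, Fe), two discouraged nutrients j (saturated fat, sodium), each
term a percent of the daily (maximum) recommended intake.  Encouraged
terms are capped at 100 % of daily value by default; discouraged terms
are never capped.  Scores of protein-rich foods then serve as
functional units: impacts per kg are rescaled to impacts per
1000 score units, and iso-nutritional substitution amounts follow from
score ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ImpactVector

__all__ = [
    "QUALIFYING_NUTRIENTS",
    "DISQUALIFYING_NUTRIENTS",
    "NutrientProfile",
    "ReferenceIntakes",
    "QNRFScore",
    "qnrf_score",
    "substitution_factor",
    "nutritional_fu_convert",
    "meal_score",
    "DEFAULT_REFERENCE_INTAKES",
]

#: The ten encouraged nutrients, in their DRI units (g for fiber,
#: otherwise the unit of the matching ReferenceIntakes entry).
QUALIFYING_NUTRIENTS: tuple[str, ...] = (
    "fiber",
    "vitamin_a",
    "vitamin_b9",
    "vitamin_b12",
    "vitamin_e",
    "vitamin_d",
    "zinc",
    "magnesium",
    "calcium",
    "iron",
)

DISQUALIFYING_NUTRIENTS: tuple[str, ...] = ("saturated_fat", "sodium")


@dataclass(frozen=True)
class NutrientProfile:
    """Composition of 100 g of edible food.

    ``diaas`` is a fraction (0.90, not 90); ``None`` means no published
    value, in which case the protein term falls back to DIAAS = 1 and
    the score is flagged.
    """

    protein: float  # g / 100 g
    diaas: float | None = None  # fraction; None = unknown
    qualifying: dict[str, float] = field(default_factory=dict)
    saturated_fat: float = 0.0  # g / 100 g
    sodium: float = 0.0  # mg / 100 g

    def __post_init__(self) -> None:
        unknown = set(self.qualifying) - set(QUALIFYING_NUTRIENTS)
        if unknown:
            raise KeyError(f"unknown qualifying nutrients: {sorted(unknown)}")
        for name, val in {"protein": self.protein, "saturated_fat": self.saturated_fat,
                          "sodium": self.sodium, **self.qualifying}.items():
            if val < 0:
                raise ValueError(f"negative amount for {name}")
        if self.diaas is not None and not 0 <= self.diaas <= 1.5:
            raise ValueError("diaas must be a fraction in [0, 1.5]")

    def scaled(self, factor: float) -> "NutrientProfile":
        return NutrientProfile(
            protein=self.protein * factor,
            diaas=self.diaas,
            qualifying={k: v * factor for k, v in self.qualifying.items()},
            saturated_fat=self.saturated_fat * factor,
            sodium=self.sodium * factor,
        )


@dataclass(frozen=True)
class ReferenceIntakes:
    """Daily recommended intakes (DRI) and maximum recommended intakes
    (MRI), one value per scored nutrient; all positive."""

    protein: float  # g/day
    qualifying: dict[str, float] = field(default_factory=dict)
    saturated_fat: float = 20.0  # g/day (MRI)
    sodium: float = 2400.0  # mg/day (MRI)

    def __post_init__(self) -> None:
        missing = set(QUALIFYING_NUTRIENTS) - set(self.qualifying)
        if missing:
            raise KeyError(f"reference intakes missing for: {sorted(missing)}")
        for name, val in {"protein": self.protein, "saturated_fat": self.saturated_fat,
                          "sodium": self.sodium, **self.qualifying}.items():
            if val <= 0:
                raise ValueError(f"reference intake for {name} must be positive")


#: Adult single-column reference table shipped as a replaceable default.
#: Values are EFSA-style placeholder DRIs for a generic adult; any
#: score meant to match a published figure should be computed from the
#: intake table that publication used.
DEFAULT_REFERENCE_INTAKES = ReferenceIntakes(
    protein=50.0,  # g
    qualifying={
        "fiber": 30.0,  # g
        "vitamin_a": 800.0,  # ug RE
        "vitamin_b9": 400.0,  # ug
        "vitamin_b12": 2.5,  # ug
        "vitamin_e": 12.0,  # mg
        "vitamin_d": 5.0,  # ug
        "zinc": 10.0,  # mg
        "magnesium": 375.0,  # mg
        "calcium": 1000.0,  # mg
        "iron": 14.0,  # mg
    },
    saturated_fat=20.0,  # g
    sodium=2400.0,  # mg
)


@dataclass
class QNRFScore:
    """A qNRF1.10.2 score with its per-term percent contributions."""

    value: float
    components: dict[str, float]
    missing_diaas: bool = False

    def __float__(self) -> float:
        return self.value


def qnrf_score(
    profile: NutrientProfile,
    refs: ReferenceIntakes = DEFAULT_REFERENCE_INTAKES,
    cap: float | None = 100.0,
) -> QNRFScore:
    """Score 100 g of food against the reference intakes.

    ``cap`` bounds each encouraged percent-of-daily-value term (100 by
    default, ``None`` for uncapped); discouraged terms are uncapped.
    """
    diaas = 1.0 if profile.diaas is None else profile.diaas
    components: dict[str, float] = {}

    def capped(pct: float) -> float:
        return pct if cap is None else min(cap, pct)

    components["protein"] = capped(100.0 * profile.protein * diaas / refs.protein)
    for name in QUALIFYING_NUTRIENTS:
        amount = profile.qualifying.get(name, 0.0)
        components[name] = capped(100.0 * amount / refs.qualifying[name])
    components["saturated_fat"] = -100.0 * profile.saturated_fat / refs.saturated_fat
    components["sodium"] = -100.0 * profile.sodium / refs.sodium
    return QNRFScore(
        value=sum(components.values()),
        components=components,
        missing_diaas=profile.diaas is None,
    )


def substitution_factor(score_ref: float | QNRFScore, score_alt: float | QNRFScore) -> float:
    """Mass multiplier giving the amount of the alternative food that
    matches the nutritional quality of the reference food.

    amount_alt = factor * amount_ref, factor = score_ref / score_alt.
    """
    ref, alt = float(score_ref), float(score_alt)
    if alt <= 0:
        raise ValueError("alternative food must have a positive score")
    return ref / alt


def nutritional_fu_convert(
    impact_per_kg: ImpactVector, score_per_100g: float | QNRFScore
) -> ImpactVector:
    """Rescale per-kg impacts to the nutritional functional unit of
    1000 score units: impact_per_kg * 1000 / (10 * score)."""
    score = float(score_per_100g)
    if score <= 0:
        raise ValueError("nutritional FU conversion requires a positive score")
    return impact_per_kg * (1000.0 / (10.0 * score))


def meal_score(
    ingredients: list[tuple[NutrientProfile, float]],
    refs: ReferenceIntakes = DEFAULT_REFERENCE_INTAKES,
    cap: float | None = 100.0,
    cooked_mass: float | None = None,
) -> QNRFScore:
    """Score of a composed meal: mass-weighted per-100 g profile of the
    mix, then one qNRF evaluation (capping applies after mixing).

    ``cooked_mass`` overrides the denominator when the finished dish
    weighs less than the sum of its parts (water loss); the DIAAS of
    the blend is the protein-weighted mean, with missing values
    entering at 1.0 and flagging the result.
    """
    if not ingredients:
        raise ValueError("meal has no ingredients")
    total_mass = cooked_mass if cooked_mass is not None else sum(m for _, m in ingredients)
    if total_mass <= 0:
        raise ValueError("meal mass must be positive")
    protein = sum(p.protein * m for p, m in ingredients) / total_mass
    qualifying = {
        name: sum(p.qualifying.get(name, 0.0) * m for p, m in ingredients) / total_mass
        for name in QUALIFYING_NUTRIENTS
    }
    sfa = sum(p.saturated_fat * m for p, m in ingredients) / total_mass
    sodium = sum(p.sodium * m for p, m in ingredients) / total_mass
    protein_mass = sum(p.protein * m for p, m in ingredients)
    missing = any(p.diaas is None for p, _ in ingredients if p.protein > 0)
    if protein_mass > 0:
        diaas = (
            sum((1.0 if p.diaas is None else p.diaas) * p.protein * m for p, m in ingredients)
            / protein_mass
        )
    else:
        diaas = 1.0
    blend = NutrientProfile(
        protein=protein, diaas=diaas, qualifying=qualifying, saturated_fat=sfa, sodium=sodium
    )
    score = qnrf_score(blend, refs, cap)
    score.missing_diaas = missing
    return score
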