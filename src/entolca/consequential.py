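"""Consequential modeling by system expansion.

A demand increase for mealworm products is evaluated against marginal
background intensities (the suppliers that actually respond to the
extra demand), and the coproducts are credited with the burdens of the
market products they displace: frass substitutes a commercial organic
fertilizer on an organic-matter basis, dried residue substitutes bird
feed on a protein basis.  Net impact = marginal gross - displacement
credits; no allocation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ImpactVector, Product, ProductSystem
from .engine import compute_impacts, scale_inventory
from .tables import BackgroundIntensityTable, CharacterizationTable

__all__ = [
    "DisplacementLink",
    "displacement_ratio",
    "ExpandedResult",
    "expand_system",
    "credit_report",
    "default_displacement_links",
]

#: Attributes of the displaced commercial organic fertilizer
#: (NPK 3/2/3, 52.7% organic matter).
COMMERCIAL_FERTILIZER = Product(
    "commercial organic fertilizer", "kg", organic_matter=0.527, npk=(3.0, 2.0, 3.0)
)
#: Generic displaced bird feed; the protein content is a synthetic
#: cereal-feed figure (the credit is negligible either way).
POULTRY_FEED = Product("poultry feed", "kg", protein_content=26.5)


def displacement_ratio(coproduct: Product, displaced: Product, basis: str) -> float:
    """kg of displaced market product avoided per kg of coproduct.

    ratio = attribute(coproduct) / attribute(displaced), where the
    attribute is ``organic_matter`` (fertilizer substitution) or
    ``protein`` (feed substitution).
    """
    getters = {
        "organic_matter": lambda p: p.organic_matter,
        "protein": lambda p: p.protein_content,
    }
    if basis not in getters:
        raise ValueError(f"unknown displacement basis {basis!r}")
    a, b = getters[basis](coproduct), getters[basis](displaced)
    if a is None or b is None:
        raise ValueError(
            f"both {coproduct.name!r} and {displaced.name!r} must carry the "
            f"{basis} attribute"
        )
    if b == 0:
        raise ValueError(f"displaced product {displaced.name!r} has zero {basis}")
    return a / b


@dataclass(frozen=True)
class DisplacementLink:
    """One coproduct-displaces-market-product relation."""

    coproduct: Product
    displaced: Product
    basis: str

    @property
    def ratio(self) -> float:
        return displacement_ratio(self.coproduct, self.displaced, self.basis)


def default_displacement_links(system: ProductSystem) -> list[DisplacementLink]:
    """The study's two substitutions, bound to the system's own coproducts."""
    links = []
    for prod, _ in system.coproducts():
        if prod.name == "mealworm frass":
            links.append(DisplacementLink(prod, COMMERCIAL_FERTILIZER, "organic_matter"))
        elif prod.name == "dried mealworm residue":
            links.append(DisplacementLink(prod, POULTRY_FEED, "protein"))
    return links


@dataclass
class ExpandedResult:
    """Consequential evaluation: marginal gross, per-link credits, net."""

    gross: ImpactVector
    credits: dict[str, ImpactVector]
    net: ImpactVector
    coproduct_amounts: dict[str, float] = field(default_factory=dict)

    @property
    def total_credit(self) -> ImpactVector:
        total = ImpactVector.zero()
        for vec in self.credits.values():
            total = total + vec
        return total


def expand_system(
    system: ProductSystem,
    links: list[DisplacementLink],
    marginal_background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
    fu_amount: float = 1.0,
) -> ExpandedResult:
    """Evaluate the expanded system: marginal gross minus displacement
    credits for every linked coproduct."""
    gross = compute_impacts(system, fu_amount, marginal_background, cfs)
    inv = scale_inventory(system, fu_amount)
    credits: dict[str, ImpactVector] = {}
    amounts: dict[str, float] = {}
    for link in links:
        name = link.coproduct.name
        if name not in inv.outputs:
            raise ValueError(f"displacement link references absent coproduct {name!r}")
        amount = inv.outputs[name]
        credit = amount * link.ratio * marginal_background.intensity(link.displaced.name)
        credits[name] = credits.get(name, ImpactVector.zero()) + credit
        amounts[name] = amount
    net = gross
    for vec in credits.values():
        net = net - vec
    return ExpandedResult(gross=gross, credits=credits, net=net, coproduct_amounts=amounts)


def credit_report(result: ExpandedResult) -> dict[str, dict[str, float]]:
    """Per-link credits as a fraction of the marginal gross burden,
    category by category (zero where the gross burden is zero)."""
    out: dict[str, dict[str, float]] = {}
    gross = result.gross.as_dict()
    for name, vec in result.credits.items():
        out[name] = {
            cat: (val / gross[cat] if gross[cat] != 0 else 0.0)
            for cat, val in vec.as_dict().items()
        }
    return out
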