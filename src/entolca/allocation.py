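"""Attributional multifunctionality handling.

The farm delivers three sellable products per kilogram of larvae: the
larvae themselves, 2.50 kg of frass (sold as organic fertilizer) and
3.18e-2 kg of dried residue (sold as bird feed).  Burdens of the stages
shared up to the end of rearing are partitioned among the three by
economic value (TM_AE), by mass (TM_AM), or not at all (TM_AW, all
burdens on the larvae); product-specific stages (killing/blanching for
the larvae, drying for frass and residue) stay with their owner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ImpactVector, ProductSystem, Scenario
from .engine import contribution_by_stage, process_scales, scale_inventory
from .tables import BackgroundIntensityTable, CharacterizationTable

__all__ = [
    "AllocationResult",
    "allocation_fractions",
    "split_shared_specific",
    "allocate",
    "wheat_bran_upstream_allocation",
    "DEFAULT_STAGE_OWNERS",
]

#: Ownership of non-shared stages.  "main" stages follow the main
#: product chain; "coproducts_by_mass" stages are divided among the
#: coproducts in proportion to their masses.
DEFAULT_STAGE_OWNERS: dict[str, str] = {
    "killing_blanching": "main",
    "drying": "coproducts_by_mass",
    "ingredients": "main",
    "cooking": "main",
}


def allocation_fractions(
    coproducts: list[tuple[str, float, float | None]], basis: str
) -> dict[str, float]:
    """Partitioning fractions over coproducts given as (name, mass, price).

    ``economic``: value shares m_k p_k / sum(m_j p_j); ``mass``: mass
    shares; ``none``: everything to the first (main) product.
    Fractions are non-negative and sum to one.
    """
    if not coproducts:
        raise ValueError("no coproducts to allocate over")
    names = [n for n, _, _ in coproducts]
    if basis == "none":
        return {n: (1.0 if i == 0 else 0.0) for i, n in enumerate(names)}
    if basis == "mass":
        weights = [m for _, m, _ in coproducts]
    elif basis == "economic":
        missing = [n for n, _, p in coproducts if p is None]
        if missing:
            raise ValueError(f"economic allocation requires prices; missing for {missing}")
        weights = [m * p for _, m, p in coproducts]
    else:
        raise ValueError(f"unknown allocation basis {basis!r}")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError(f"total {basis} weight is zero")
    return {n: w / total for n, w in zip(names, weights)}


def wheat_bran_upstream_allocation(
    flour_price: float, bran_price: float, flour_mass: float, bran_mass: float
) -> dict[str, float]:
    """Economic split of wheat-milling burdens between flour and bran.

    Exposed so the "wheat bran" background intensity can be documented
    as carrying only the bran-allocated share of the milling system.
    """
    return allocation_fractions(
        [("flour", flour_mass, flour_price), ("bran", bran_mass, bran_price)],
        basis="economic",
    )


@dataclass
class AllocationResult:
    """Outcome of an attributional allocation over one system."""

    basis: str
    main_product: str
    fractions: dict[str, float]
    shared: ImpactVector
    specific: dict[str, ImpactVector]
    per_product: dict[str, ImpactVector]
    gross: ImpactVector
    coproduct_amounts: dict[str, float] = field(default_factory=dict)

    @property
    def main(self) -> ImpactVector:
        return self.per_product[self.main_product]


def _scaled_coproducts(system: ProductSystem, fu_amount: float) -> list[tuple[str, float, float | None]]:
    """(name, mass, price) of each coproduct scaled to the functional unit."""
    scales = process_scales(system, fu_amount)
    out = []
    consumed = {sid for p in system.processes for sid, _ in p.foreground_inputs}
    for proc in system.processes:
        s = scales[proc.id]
        for k, (prod, amt) in enumerate(proc.outputs):
            if prod.name == system.reference_product.name:
                continue
            if k == 0 and proc.id in consumed:
                continue
            out.append((prod.name, s * amt, prod.price))
    return out


def _drying_owner_map(system: ProductSystem) -> dict[str, dict[str, float]]:
    """Which coproduct owns what share of each coproduct-specific stage."""
    owners: dict[str, dict[str, float]] = {}
    copros = _scaled_coproducts(system, 1.0)
    total_mass = sum(m for _, m, _ in copros)
    for stage, owner in DEFAULT_STAGE_OWNERS.items():
        if owner == "coproducts_by_mass" and total_mass > 0:
            owners[stage] = {n: m / total_mass for n, m, _ in copros}
    return owners


def split_shared_specific(
    system: ProductSystem,
    scenario: Scenario,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
    fu_amount: float = 1.0,
    main_product: str | None = None,
) -> tuple[ImpactVector, dict[str, ImpactVector]]:
    """Split gross impacts into the shared pool and per-owner specific parts.

    Shared = stages inside ``scenario.shared_boundary``; the remainder is
    grouped under the main product (killing/blanching and any meal
    stages) or divided among the coproducts by mass (drying).
    """
    main = main_product or _default_main_product(system)
    report = contribution_by_stage(system, fu_amount, background, cfs)
    shared = ImpactVector.zero()
    specific: dict[str, ImpactVector] = {main: ImpactVector.zero()}
    by_mass = _drying_owner_map(system)
    for stage in report.absolute.index:
        vec = report.stage_vector(stage)
        if stage in scenario.shared_boundary:
            shared = shared + vec
        elif stage in by_mass:
            for name, w in by_mass[stage].items():
                specific[name] = specific.get(name, ImpactVector.zero()) + vec * w
        elif DEFAULT_STAGE_OWNERS.get(stage) == "main" or stage not in DEFAULT_STAGE_OWNERS:
            if stage not in DEFAULT_STAGE_OWNERS:
                raise ValueError(f"post-boundary stage {stage!r} has no configured owner")
            specific[main] = specific[main] + vec
    return shared, specific


def _default_main_product(system: ProductSystem) -> str:
    return system.reference_product.name


def allocate(
    system: ProductSystem,
    scenario: Scenario,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
    fu_amount: float = 1.0,
    main_product: str | None = None,
) -> AllocationResult:
    """Full attributional evaluation of one scenario.

    Per coproduct: allocated impact = fraction x shared + own specific.
    Under basis ``none`` the main product carries shared plus *all*
    specific burdens, coproduct drying included.

    ``main_product`` designates the product whose chain the
    main-specific stages follow; it defaults to the reference product
    (for the meal system the mealworm coproduct split still applies,
    with the meal as the main chain).
    """
    if scenario.strategy == "expansion":
        raise ValueError("expansion scenarios are handled by entolca.consequential")
    main = main_product or _default_main_product(system)
    shared, specific = split_shared_specific(
        system, scenario, background, cfs, fu_amount, main_product=main
    )
    copros = _scaled_coproducts(system, fu_amount)
    inv = scale_inventory(system, fu_amount)
    carrier_name, carrier_price = _allocation_carrier(system)
    carrier_mass = inv.outputs.get(carrier_name, fu_amount)

    listing = [(carrier_name, carrier_mass, carrier_price)] + list(copros)
    fractions = allocation_fractions(listing, basis=scenario.strategy)

    per_product: dict[str, ImpactVector] = {}
    gross = shared
    for vec in specific.values():
        gross = gross + vec
    if scenario.strategy == "none":
        for name, _, _ in copros:
            per_product[name] = ImpactVector.zero()
        per_product[main] = gross
    else:
        per_product[main] = fractions[carrier_name] * shared + specific.get(
            main, ImpactVector.zero()
        )
        for name, _, _ in copros:
            per_product[name] = fractions[name] * shared + specific.get(
                name, ImpactVector.zero()
            )
    return AllocationResult(
        basis=scenario.strategy,
        main_product=main,
        fractions=fractions,
        shared=shared,
        specific=specific,
        per_product=per_product,
        gross=gross,
        coproduct_amounts={n: m for n, m, _ in copros},
    )


def _allocation_carrier(system: ProductSystem) -> tuple[str, float | None]:
    """The product representing the main chain in the multifunctional split.

    This is the primary output of the killing/blanching stage -- the
    larvae -- whenever the system contains one (the farm itself, or a
    meal built on top of it); otherwise the reference product.  Its
    scaled mass and price enter the allocation fractions alongside the
    coproducts.
    """
    for proc in system.processes:
        if proc.stage_label == "killing_blanching":
            prod, _ = proc.primary_output
            return prod.name, prod.price
    return system.reference_product.name, system.reference_product.price
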