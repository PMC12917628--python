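"""Core domain types for the insect-food LCA pipeline.

The model world is small and explicit: six midpoint impact categories, a
foreground product system described as an acyclic graph of processes
(each normalised to one unit of its primary output), a background
intensity table giving the impact vector embodied in one unit of each
purchased product, and a characterization table converting direct
elementary emissions (N2O, CO2, NH3, ...) into impact-category units.

No computation lives here beyond validation and impact-vector
arithmetic; evaluation is in :mod:`entolca.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "CATEGORIES",
    "CATEGORY_UNITS",
    "ImpactVector",
    "Product",
    "ForegroundProcess",
    "ProductSystem",
    "Scenario",
    "SCENARIOS",
    "validate_system",
]

#: The six midpoint impact categories carried through the whole pipeline,
#: in fixed order: global warming, freshwater eutrophication, marine
#: eutrophication, land use, water scarcity, fossil resource use.
CATEGORIES: tuple[str, ...] = ("GWP", "FEP", "MEP", "LU", "WU", "ADPfossil")

CATEGORY_UNITS: dict[str, str] = {
    "GWP": "kg CO2 equiv",
    "FEP": "kg P equiv",
    "MEP": "kg N equiv",
    "LU": "Pt",
    "WU": "m3",
    "ADPfossil": "MJ",
}

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class ImpactVector:
    """One value per impact category, each in that category's own unit.

    Arithmetic is category-wise; there is deliberately no way to collapse
    the vector to a single number, because the categories are not
    commensurable.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(CATEGORIES):
            raise ValueError(
                f"expected {len(CATEGORIES)} category values, got {len(self.values)}"
            )

    @classmethod
    def zero(cls) -> "ImpactVector":
        return cls(values=(0.0,) * len(CATEGORIES))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ImpactVector":
        unknown = set(d) - set(CATEGORIES)
        if unknown:
            raise KeyError(f"unknown impact categories: {sorted(unknown)}")
        return cls(values=tuple(float(d.get(c, 0.0)) for c in CATEGORIES))

    @classmethod
    def from_array(cls, a) -> "ImpactVector":
        return cls(values=tuple(float(x) for x in np.asarray(a, dtype=float)))

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CATEGORIES, self.values))

    def __getitem__(self, category: str) -> float:
        return self.values[_CAT_INDEX[category]]

    def __add__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(tuple(a + b for a, b in zip(self.values, other.values)))

    def __sub__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(tuple(a - b for a, b in zip(self.values, other.values)))

    def __mul__(self, k: float) -> "ImpactVector":
        return ImpactVector(tuple(a * float(k) for a in self.values))

    __rmul__ = __mul__

    def isclose(self, other: "ImpactVector", rtol: float = 1e-9, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.as_array(), other.as_array(), rtol=rtol, atol=atol))


@dataclass(frozen=True)
class Product:
    """A product flow: either a system output (larvae, frass, a meal) or a
    purchased background product (feed, electricity, transport service).

    Optional attributes feed downstream steps: ``price`` (EUR/kg) drives
    economic allocation, ``protein_content`` (g/100 g) and
    ``organic_matter`` (mass fraction) drive displacement ratios, ``npk``
    documents fertilizer equivalence.
    """

    name: str
    reference_unit: str = "kg"
    price: float | None = None  # EUR per kg
    protein_content: float | None = None  # g per 100 g
    organic_matter: float | None = None  # mass fraction, <= 1
    npk: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.price is not None and self.price < 0:
            raise ValueError(f"negative price for {self.name}")
        if self.organic_matter is not None and not 0 <= self.organic_matter <= 1:
            raise ValueError(f"organic_matter of {self.name} must be a fraction in [0, 1]")
        if self.protein_content is not None and self.protein_content < 0:
            raise ValueError(f"negative protein content for {self.name}")

    def with_price(self, price: float) -> "Product":
        return replace(self, price=price)


#: Stage taxonomy used for contribution reporting.  The farm stages map
#: one-to-one onto the reporting granularity of the contribution figures
#: (feed production; mealworm production = rearing + killing/blanching +
#: drying; cleaning; facilities maintenance; waste management), and the
#: meal adds its own three stages.
STAGE_LABELS: tuple[str, ...] = (
    "feed_production",
    "rearing",
    "killing_blanching",
    "drying",
    "cleaning",
    "facilities_maintenance",
    "waste_management",
    "ingredients",
    "cooking",
)


@dataclass
class ForegroundProcess:
    """A foreground unit process, normalised to one unit of its primary
    output.

    ``background_inputs`` are (product name, amount) pairs priced against
    the background intensity table; ``direct_emissions`` are elementary
    flows characterized directly; ``foreground_inputs`` reference other
    foreground processes by id.  The first entry of ``outputs`` is the
    primary output.
    """

    id: str
    stage_label: str
    outputs: list[tuple[Product, float]]
    background_inputs: list[tuple[str, float]] = field(default_factory=list)
    direct_emissions: list[tuple[str, float]] = field(default_factory=list)
    foreground_inputs: list[tuple[str, float]] = field(default_factory=list)

    @property
    def primary_output(self) -> tuple[Product, float]:
        return self.outputs[0]


@dataclass
class ProductSystem:
    """A set of foreground processes delivering one reference product."""

    processes: list[ForegroundProcess]
    reference_product: Product
    reference_amount: float = 1.0

    def process_map(self) -> dict[str, ForegroundProcess]:
        return {p.id: p for p in self.processes}

    def producer_of(self, product_name: str) -> ForegroundProcess | None:
        hits = [
            p
            for p in self.processes
            if any(prod.name == product_name for prod, _ in p.outputs)
        ]
        if len(hits) != 1:
            return None
        return hits[0]

    def reference_process(self) -> ForegroundProcess:
        proc = self.producer_of(self.reference_product.name)
        if proc is None:
            raise ValueError(
                f"reference product {self.reference_product.name!r} must be produced "
                "by exactly one process"
            )
        return proc

    def graph(self) -> nx.DiGraph:
        """Directed graph with an edge supplier -> consumer per foreground link."""
        g = nx.DiGraph()
        g.add_nodes_from(p.id for p in self.processes)
        for proc in self.processes:
            for supplier_id, _ in proc.foreground_inputs:
                g.add_edge(supplier_id, proc.id)
        return g

    def coproducts(self) -> list[tuple[Product, float]]:
        """Sellable coproducts: outputs that are neither the reference
        product nor an intermediate consumed through a foreground link.

        Primary outputs of internally consumed processes (including
        synthetic stage "services") are intermediates; secondary outputs
        ride along with demand and leave the system as coproducts.
        Amounts are per unit activity of the producing process.
        """
        consumed_process_ids = {
            supplier_id for p in self.processes for supplier_id, _ in p.foreground_inputs
        }
        out: list[tuple[Product, float]] = []
        for proc in self.processes:
            for k, (prod, amt) in enumerate(proc.outputs):
                if prod.name == self.reference_product.name:
                    continue
                is_primary = k == 0
                if is_primary and proc.id in consumed_process_ids:
                    continue  # intermediate
                out.append((prod, amt))
        return out


@dataclass(frozen=True)
class Scenario:
    """A named multifunctionality-handling configuration.

    ``strategy`` is ``economic``, ``mass`` or ``none`` for the
    attributional scenarios (allocation basis) or ``expansion`` for the
    consequential one.  ``shared_boundary`` lists the stage labels whose
    burdens are shared among coproducts before allocation; it is ignored
    under expansion.
    """

    name: str
    strategy: str
    shared_boundary: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strategy not in {"economic", "mass", "none", "expansion"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")


#: Stages shared among the farm coproducts up to the end of rearing.
DEFAULT_SHARED_BOUNDARY = frozenset(
    {"feed_production", "rearing", "cleaning", "facilities_maintenance", "waste_management"}
)

SCENARIOS: dict[str, Scenario] = {
    "TM_AE": Scenario("TM_AE", "economic", DEFAULT_SHARED_BOUNDARY),
    "TM_AM": Scenario("TM_AM", "mass", DEFAULT_SHARED_BOUNDARY),
    "TM_AW": Scenario("TM_AW", "none", DEFAULT_SHARED_BOUNDARY),
    "TM_C": Scenario("TM_C", "expansion"),
}


def validate_system(system: ProductSystem) -> list[str]:
    """Check all structural invariants; return findings (empty iff valid).

    Findings name the offending process or field.  The function never
    raises and never mutates its input.
    """
    findings: list[str] = []
    seen_ids: set[str] = set()
    for proc in system.processes:
        if proc.id in seen_ids:
            findings.append(f"duplicate process id {proc.id!r}")
        seen_ids.add(proc.id)
        if not proc.outputs:
            findings.append(f"process {proc.id!r} has no outputs")
        for prod, amt in proc.outputs:
            if amt < 0:
                findings.append(f"process {proc.id!r}: negative output amount for {prod.name!r}")
        for name, amt in proc.background_inputs:
            if amt < 0:
                findings.append(f"process {proc.id!r}: negative background input {name!r}")
        for name, amt in proc.direct_emissions:
            if amt < 0:
                findings.append(f"process {proc.id!r}: negative emission {name!r}")
        for supplier_id, amt in proc.foreground_inputs:
            if amt < 0:
                findings.append(f"process {proc.id!r}: negative foreground input {supplier_id!r}")
            if supplier_id not in {p.id for p in system.processes}:
                findings.append(
                    f"process {proc.id!r}: foreground input references missing process {supplier_id!r}"
                )

    producers = [
        p
        for p in system.processes
        if any(prod.name == system.reference_product.name for prod, _ in p.outputs)
    ]
    if len(producers) != 1:
        findings.append(
            f"ambiguous reference: product {system.reference_product.name!r} produced by "
            f"{len(producers)} processes"
        )

    g = system.graph()
    # only check cycles among processes that actually exist
    g = g.subgraph(seen_ids).copy()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        findings.append("cycle in foreground links: " + " -> ".join(e[0] for e in cyc))
    return findings
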