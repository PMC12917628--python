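"""Inventory I/O: CSV (de)serialization of product systems and tables,
plus the built-in foreground fixtures.

The two fixtures encode the study's foreground inventories: a mealworm
(*Tenebrio molitor*) farm normalised to 1 kg of larvae ready for human
consumption, and a mealworm-based lasagna meal whose mince input is
produced by the farm system.  All amounts are the inventory values as
collected from the producer; background products stand for aggregated
upstream datasets and are priced against a
:class:`~entolca.tables.BackgroundIntensityTable`.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import pandas as pd

from .core import (
    CATEGORIES,
    ForegroundProcess,
    Product,
    ProductSystem,
)
from .tables import BackgroundIntensityTable

__all__ = [
    "SCHEMA_COLUMNS",
    "save_system",
    "load_system",
    "load_background",
    "save_background",
    "load_prices",
    "load_nutrients",
    "fixture_mealworm_farm",
    "fixture_lasagna",
    "FARM_PRICES",
    "WASTE_DESTINATION_SHARES",
    "RESIDUAL_ELECTRICITY_MIX",
]

SCHEMA_COLUMNS = [
    "process_id",
    "stage_label",
    "io_direction",
    "item_name",
    "item_kind",
    "amount",
    "unit",
]

KNOWN_UNITS = {"kg", "L", "kWh", "km·kg", "unit", "m2", "m3", "MJ", "Pt"}

# --------------------------------------------------------------------------
# system serialization


def save_system(system: ProductSystem, path: str | Path | None = None) -> str:
    """Serialize a system to the row-per-flow CSV schema.

    Canonical order: processes as listed, and within each process
    outputs, background inputs, foreground inputs, then emissions.  The
    first output row of the file is the reference product, and the
    reference process is written first.
    """
    rows = []
    ref = system.reference_process()
    ordered = [ref] + [p for p in system.processes if p.id != ref.id]
    for proc in ordered:
        for prod, amt in proc.outputs:
            rows.append((proc.id, proc.stage_label, "output", prod.name, "product", amt, prod.reference_unit))
        for name, amt in proc.background_inputs:
            rows.append((proc.id, proc.stage_label, "input", name, "background", amt, _unit_of(name)))
        for supplier, amt in proc.foreground_inputs:
            rows.append((proc.id, proc.stage_label, "input", supplier, "foreground", amt, "unit"))
        for name, amt in proc.direct_emissions:
            rows.append((proc.id, proc.stage_label, "emission", name, "elementary", amt, "kg"))
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    text = df.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_system(source: str | Path) -> ProductSystem:
    """Parse a system from the CSV schema; inverse of :func:`save_system`.

    Raises ``ValueError`` naming the offending row/column on schema
    violations and on unknown units.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    df = pd.read_csv(
        _stdio.StringIO(text), dtype={"amount": float}, keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"inventory file missing required columns: {missing}")
    procs: dict[str, ForegroundProcess] = {}
    reference: Product | None = None
    for i, row in df.iterrows():
        unit = str(row["unit"])
        if unit not in KNOWN_UNITS:
            raise ValueError(f"row {i}: unknown unit {unit!r}")
        pid = str(row["process_id"])
        if pid not in procs:
            procs[pid] = ForegroundProcess(id=pid, stage_label=str(row["stage_label"]), outputs=[])
        proc = procs[pid]
        direction = row["io_direction"]
        kind = row["item_kind"]
        name = str(row["item_name"])
        amount = float(row["amount"])
        if direction == "output" and kind == "product":
            prod = Product(name=name, reference_unit=unit)
            proc.outputs.append((prod, amount))
            if reference is None:
                reference = prod
        elif direction == "input" and kind == "background":
            proc.background_inputs.append((name, amount))
        elif direction == "input" and kind == "foreground":
            proc.foreground_inputs.append((name, amount))
        elif direction == "emission" and kind == "elementary":
            proc.direct_emissions.append((name, amount))
        else:
            raise ValueError(
                f"row {i}: invalid io_direction/item_kind pair ({direction!r}, {kind!r})"
            )
    if reference is None:
        raise ValueError("inventory file contains no product output row")
    return ProductSystem(processes=list(procs.values()), reference_product=reference)


# --------------------------------------------------------------------------
# auxiliary tables


def load_background(source: str | Path) -> BackgroundIntensityTable:
    """Read an intensity table: product_name, unit, one column per category."""
    df = pd.read_csv(source)
    if "product_name" not in df.columns:
        raise ValueError("background file missing 'product_name' column")
    missing = [c for c in CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"background file missing impact-category columns: {missing}")
    if df["product_name"].duplicated().any():
        dups = sorted(df.loc[df["product_name"].duplicated(), "product_name"])
        raise ValueError(f"duplicate products in background file: {dups}")
    units = (
        dict(zip(df["product_name"], df["unit"])) if "unit" in df.columns else {}
    )
    frame = df.set_index("product_name")[list(CATEGORIES)]
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"missing intensity cells for: {bad}")
    return BackgroundIntensityTable(frame=frame, units=units)


def save_background(table: BackgroundIntensityTable, path: str | Path | None = None) -> str:
    df = table.frame.copy()
    df.insert(0, "unit", [table.units.get(p, "kg") for p in df.index])
    df.index.name = "product_name"
    text = df.to_csv()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_prices(source: str | Path) -> dict[str, float]:
    """Read product prices (EUR/kg) from a two-column CSV."""
    df = pd.read_csv(source)
    for col in ("product_name", "price_eur_per_kg"):
        if col not in df.columns:
            raise ValueError(f"prices file missing {col!r} column")
    if df["product_name"].duplicated().any():
        raise ValueError("duplicate products in prices file")
    return dict(zip(df["product_name"], df["price_eur_per_kg"].astype(float)))


def load_nutrients(source: str | Path) -> pd.DataFrame:
    """Read per-100 g nutrient composition profiles, one row per food."""
    df = pd.read_csv(source)
    if "food_name" not in df.columns:
        raise ValueError("nutrients file missing 'food_name' column")
    if df["food_name"].duplicated().any():
        raise ValueError("duplicate foods in nutrients file")
    return df.set_index("food_name")


# --------------------------------------------------------------------------
# fixtures

#: Farm-gate prices (EUR per kg) used for economic allocation: the
#: insect price is the European market average, and the dried residue is
#: priced like frass because it undergoes the same drying operation.
FARM_PRICES: dict[str, float] = {
    "yellow mealworm larvae": 221.0,  # 22.10 EUR/100 g
    "mealworm frass": 24.4,  # 2.44 EUR/100 g
    "dried mealworm residue": 24.4,
}

#: Destination shares applied to discarded organic feed residues,
#: following national waste-management statistics.
WASTE_DESTINATION_SHARES: dict[str, float] = {
    "organic waste, recycling": 0.0567,
    "organic waste, composting": 0.2290,
    "organic waste, landfill": 0.5815,
    "organic waste, incineration": 0.1328,
}

#: Documentation-only metadata: what the "electricity, residual ES"
#: background intensity represents (grid electricity left after green
#: demand is served) -- approx. 58% fossil, 36% nuclear, 6% renewable.
RESIDUAL_ELECTRICITY_MIX: dict[str, float] = {"fossil": 0.58, "nuclear": 0.36, "renewable": 0.06}

#: Units for every background product referenced by the fixtures.
BACKGROUND_UNITS: dict[str, str] = {
    "wheat bran": "kg",
    "oat": "kg",
    "corn": "kg",
    "soybean": "kg",
    "potato": "kg",
    "barley": "kg",
    "transport, lorry": "km·kg",
    "electricity, climatic chamber": "kWh",
    "rearing boxes (PP)": "kg",
    "electricity, killing": "kWh",
    "electricity, blanching": "kWh",
    "electricity, drying": "kWh",
    "water, feed cleaning": "L",
    "bleach": "L",
    "water, facilities maintenance": "L",
    "floor cleaner": "L",
    "antimite": "L",
    "land occupation": "m2",
    "organic waste, recycling": "kg",
    "organic waste, composting": "kg",
    "organic waste, landfill": "kg",
    "organic waste, incineration": "kg",
    "wastewater treatment": "L",
    # meal ingredients
    "olive oil": "kg",
    "onion": "kg",
    "garlic": "kg",
    "wheat flour": "kg",
    "meat stock": "L",
    "tomato puree": "kg",
    "thyme": "kg",
    "chopped tomatoes": "kg",
    "butter": "kg",
    "milk": "L",
    "mustard": "kg",
    "parmesan cheese": "kg",
    "lasagna sheets": "kg",
    "cheddar cheese": "kg",
    "electricity, stove": "kWh",
    "electricity, oven": "kWh",
    "tap water": "L",
    # consequential displaced products
    "commercial organic fertilizer": "kg",
    "poultry feed": "kg",
}


def _unit_of(name: str) -> str:
    return BACKGROUND_UNITS.get(name, "kg")


#: Feed-ingredient masses (kg per kg of larvae); their sum is the feed
#: conversion ratio of the farm (~4).
FEED_INPUTS: dict[str, float] = {
    "wheat bran": 2.0,
    "oat": 0.43,
    "corn": 0.62,
    "soybean": 6.76e-2,
    "potato": 0.71,
    "barley": 0.15,
}

#: Transport distances (km): shared feed route wholesaler->supplier and
#: supplier->farm, plus a separate barley route.
FEED_TRANSPORT_KM = (227.0, 5.0)
BARLEY_TRANSPORT_KM = 30.0


def fixture_mealworm_farm() -> ProductSystem:
    """Foreground inventory of the mealworm farm, per 1 kg of larvae.

    Seven stage processes feed a chain rearing -> killing/blanching; the
    drying of surplus manure and undeveloped worms rides along with the
    larvae demand and yields the two coproducts (frass 2.50 kg, dried
    residue 3.18e-2 kg).
    """
    feed_mass_shared = sum(m for n, m in FEED_INPUTS.items() if n != "barley")
    transport = feed_mass_shared * sum(FEED_TRANSPORT_KM) + FEED_INPUTS["barley"] * BARLEY_TRANSPORT_KM

    larvae = Product(
        "yellow mealworm larvae",
        "kg",
        price=FARM_PRICES["yellow mealworm larvae"],
        protein_content=19.7,
        organic_matter=0.38,
    )
    live_larvae = Product("live mealworm larvae", "kg")
    frass = Product(
        "mealworm frass",
        "kg",
        price=FARM_PRICES["mealworm frass"],
        organic_matter=0.80,
        npk=(3.0, 3.0, 3.0),
    )
    residue = Product(
        "dried mealworm residue",
        "kg",
        price=FARM_PRICES["dried mealworm residue"],
        protein_content=53.0,
        organic_matter=0.90,
    )

    feed = ForegroundProcess(
        id="farm_feed",
        stage_label="feed_production",
        outputs=[(Product("feed supply service", "unit"), 1.0)],
        background_inputs=[*FEED_INPUTS.items(), ("transport, lorry", transport)],
    )
    cleaning = ForegroundProcess(
        id="farm_cleaning",
        stage_label="cleaning",
        outputs=[(Product("cleaning service", "unit"), 1.0)],
        background_inputs=[("water, feed cleaning", 0.30), ("bleach", 1.11e-3)],
    )
    maintenance = ForegroundProcess(
        id="farm_maintenance",
        stage_label="facilities_maintenance",
        outputs=[(Product("maintenance service", "unit"), 1.0)],
        background_inputs=[
            ("water, facilities maintenance", 0.10),
            ("floor cleaner", 5.55e-4),
            ("antimite", 2.77e-4),
            ("land occupation", 7.77e-2),
        ],
    )
    organic_waste = 3.04e-2 + 1.01e-2  # dried + wet feed residues
    waste = ForegroundProcess(
        id="farm_waste",
        stage_label="waste_management",
        outputs=[(Product("waste management service", "unit"), 1.0)],
        background_inputs=[
            *((dest, organic_waste * share) for dest, share in WASTE_DESTINATION_SHARES.items()),
            ("wastewater treatment", 0.40),
        ],
    )
    rearing = ForegroundProcess(
        id="farm_rearing",
        stage_label="rearing",
        outputs=[(live_larvae, 1.0)],
        background_inputs=[
            ("electricity, climatic chamber", 1.08e-2),
            ("rearing boxes (PP)", 4e-3),
        ],
        direct_emissions=[("N2O", 2.55e-5), ("CO2", 7.58e-3), ("NH3", 1e-6)],
        foreground_inputs=[
            ("farm_feed", 1.0),
            ("farm_cleaning", 1.0),
            ("farm_maintenance", 1.0),
            ("farm_waste", 1.0),
        ],
    )
    drying = ForegroundProcess(
        id="farm_drying",
        stage_label="drying",
        outputs=[(Product("drying service", "unit"), 1.0), (frass, 2.50), (residue, 3.18e-2)],
        background_inputs=[("electricity, drying", 1.20e-3)],
    )
    killing = ForegroundProcess(
        id="farm_killing",
        stage_label="killing_blanching",
        outputs=[(larvae, 1.0)],
        background_inputs=[
            ("electricity, killing", 6.11e-2),
            ("electricity, blanching", 0.46),
        ],
        foreground_inputs=[("farm_rearing", 1.0), ("farm_drying", 1.0)],
    )
    return ProductSystem(
        processes=[feed, cleaning, maintenance, waste, rearing, drying, killing],
        reference_product=larvae,
    )


#: Lasagna recipe inventory: (product, amount) pairs, excluding the
#: mealworm mince (a foreground input) and cooking utilities.
LASAGNA_INGREDIENTS: list[tuple[str, float]] = [
    ("olive oil", 2.83e-2),
    ("onion", 0.22),
    ("garlic", 2e-2),
    ("wheat flour", 2.83e-2),
    ("meat stock", 0.15),
    ("tomato puree", 4.25e-2),
    ("thyme", 1.41e-2),
    ("chopped tomatoes", 0.80),
    ("butter", 5e-2),
    ("wheat flour", 5e-2),
    ("milk", 0.75),
    ("mustard", 1e-2),
    ("parmesan cheese", 5e-2),
    ("lasagna sheets", 0.78),
    ("cheddar cheese", 7.50e-2),
]

MEALWORM_MINCE_KG = 1.12


def fixture_lasagna(farm: ProductSystem | None = None) -> ProductSystem:
    """Foreground inventory of one mealworm lasagna meal.

    The mince enters as 1.12 kg of larvae produced by the farm system;
    everything else is a purchased ingredient or a cooking utility.
    """
    if farm is None:
        farm = fixture_mealworm_farm()
    meal = Product("lasagna", "unit")
    ingredients = ForegroundProcess(
        id="meal_ingredients",
        stage_label="ingredients",
        outputs=[(Product("ingredient supply service", "unit"), 1.0)],
        background_inputs=list(LASAGNA_INGREDIENTS),
    )
    farm_ref = farm.reference_process()
    cooking = ForegroundProcess(
        id="meal_cooking",
        stage_label="cooking",
        outputs=[(meal, 1.0)],
        background_inputs=[
            ("electricity, stove", 1.80),
            ("electricity, oven", 0.90),
            ("tap water", 5.0),
        ],
        foreground_inputs=[("meal_ingredients", 1.0), (farm_ref.id, MEALWORM_MINCE_KG)],
    )
    return ProductSystem(
        processes=[*farm.processes, ingredients, cooking],
        reference_product=meal,
    )
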