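import numpy as np
import pytest

from entolca.core import CATEGORIES, ForegroundProcess, Product, ProductSystem
from entolca.io import fixture_lasagna, fixture_mealworm_farm
from entolca.synthetic import calibrated_tables
from entolca.tables import BackgroundIntensityTable, CharacterizationTable


@pytest.fixture(scope="session")
def fixtures_bundle():
    """Calibrated background + foreground fixtures, computed once."""
    return calibrated_tables(seed=0)


@pytest.fixture()
def farm():
    return fixture_mealworm_farm()


@pytest.fixture()
def meal():
    return fixture_lasagna()


@pytest.fixture()
def empty_cfs():
    return CharacterizationTable.zeros(["N2O", "CO2", "NH3"])


def random_acyclic_system(rng: np.random.Generator, max_processes: int = 20):
    """A random acyclic product system plus matching background/CF tables.

    Processes are indexed so that links only point from lower to higher
    index (supplier -> consumer), which guarantees acyclicity; the last
    process delivers the reference product.
    """
    n = int(rng.integers(1, max_processes + 1))
    n_bg = int(rng.integers(1, 6))
    bg_names = [f"bg{i}" for i in range(n_bg)]
    em_names = ["em0", "em1"]
    processes = []
    for i in range(n):
        bg = [
            (bg_names[int(rng.integers(n_bg))], float(rng.uniform(0, 3)))
            for _ in range(int(rng.integers(0, 3)))
        ]
        em = [
            (em_names[int(rng.integers(2))], float(rng.uniform(0, 1)))
            for _ in range(int(rng.integers(0, 2)))
        ]
        fg = []
        if i > 0:
            for j in range(i):
                if rng.random() < 0.4:
                    fg.append((f"p{j}", float(rng.uniform(0.1, 2.0))))
        processes.append(
            ForegroundProcess(
                id=f"p{i}",
                stage_label="feed_production",
                outputs=[(Product(f"out{i}", "kg"), float(rng.uniform(0.5, 2.0)))],
                background_inputs=bg,
                direct_emissions=em,
                foreground_inputs=fg,
            )
        )
    system = ProductSystem(processes, Product(f"out{n-1}", "kg"))
    bg_table = BackgroundIntensityTable.from_dict(
        {name: {c: float(rng.uniform(0, 5)) for c in CATEGORIES} for name in bg_names}
    )
    cfs = CharacterizationTable.from_dict(
        {name: {c: float(rng.uniform(0, 2)) for c in CATEGORIES} for name in em_names}
    )
    return system, bg_table, cfs
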