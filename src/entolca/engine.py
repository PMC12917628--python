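"""Foreground evaluation: scaling, characterization, stage contributions.

The foreground systems here are small acyclic graphs, so evaluation is a
topological traversal: the reference process is scaled to the functional
unit, scaling factors propagate upstream through foreground links, and
every scaled background input is multiplied by its per-unit intensity
while every scaled direct emission is multiplied by its characterization
factors.  :func:`matrix_solve_oracle` re-derives the same totals through
the classical square technology-matrix solve and exists purely as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import CATEGORIES, ForegroundProcess, ImpactVector, Product, ProductSystem
from .tables import BackgroundIntensityTable, CharacterizationTable

__all__ = [
    "ScaledInventory",
    "ContributionReport",
    "process_scales",
    "scale_inventory",
    "compute_impacts",
    "process_impacts",
    "contribution_by_stage",
    "matrix_solve_oracle",
]


@dataclass
class ScaledInventory:
    """All flows of a system scaled to a functional unit.

    Amounts are aggregated per item name; ``scales`` records the
    activity level of every process (units of its primary output).
    """

    fu_amount: float
    scales: dict[str, float]
    background: dict[str, float]
    emissions: dict[str, float]
    outputs: dict[str, float]


def process_scales(system: ProductSystem, fu_amount: float) -> dict[str, float]:
    """Activity level of each process when the system delivers ``fu_amount``
    of its reference product, propagated in topological order."""
    procs = system.process_map()
    ref = system.reference_process()
    _, ref_amt = ref.primary_output
    if ref_amt == 0:
        raise ValueError(f"reference process {ref.id!r} has zero reference output")

    g = system.graph()
    order = list(nx.topological_sort(g))  # suppliers first
    scales = {pid: 0.0 for pid in procs}
    scales[ref.id] = fu_amount / ref_amt
    # walk consumers before suppliers
    for pid in reversed(order):
        proc = procs[pid]
        s = scales[pid]
        if s == 0.0:
            continue
        for supplier_id, amount in proc.foreground_inputs:
            supplier = procs[supplier_id]
            _, sup_amt = supplier.primary_output
            if sup_amt == 0:
                raise ValueError(f"process {supplier_id!r} has zero primary output")
            scales[supplier_id] += s * amount / sup_amt
    return scales


def scale_inventory(system: ProductSystem, fu_amount: float) -> ScaledInventory:
    """Scale every background input, emission and output linearly to the
    functional unit."""
    scales = process_scales(system, fu_amount)
    background: dict[str, float] = {}
    emissions: dict[str, float] = {}
    outputs: dict[str, float] = {}
    for proc in system.processes:
        s = scales[proc.id]
        for name, amt in proc.background_inputs:
            background[name] = background.get(name, 0.0) + s * amt
        for name, amt in proc.direct_emissions:
            emissions[name] = emissions.get(name, 0.0) + s * amt
        for prod, amt in proc.outputs:
            outputs[prod.name] = outputs.get(prod.name, 0.0) + s * amt
    return ScaledInventory(fu_amount, scales, background, emissions, outputs)


def process_impacts(
    proc: ForegroundProcess,
    scale: float,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
) -> ImpactVector:
    """Gross impact of one process at the given activity level."""
    total = np.zeros(len(CATEGORIES))
    for name, amt in proc.background_inputs:
        total += scale * amt * background.intensity(name).as_array()
    for name, amt in proc.direct_emissions:
        total += scale * amt * cfs.factor(name).as_array()
    return ImpactVector.from_array(total)


def compute_impacts(
    system: ProductSystem,
    fu_amount: float,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
) -> ImpactVector:
    """Gross (pre-allocation) system impact for ``fu_amount`` of the
    reference product."""
    scales = process_scales(system, fu_amount)
    total = ImpactVector.zero()
    for proc in system.processes:
        total = total + process_impacts(proc, scales[proc.id], background, cfs)
    return total


@dataclass
class ContributionReport:
    """Per-stage decomposition of a system's gross impacts.

    ``absolute`` and ``shares`` are DataFrames indexed by stage label
    with one column per impact category; shares in each category sum to
    one whenever the category total is nonzero.
    """

    absolute: pd.DataFrame
    shares: pd.DataFrame
    total: ImpactVector

    def stage_vector(self, stage: str) -> ImpactVector:
        if stage not in self.absolute.index:
            return ImpactVector.zero()
        return ImpactVector.from_array(self.absolute.loc[stage].to_numpy())


def contribution_by_stage(
    system: ProductSystem,
    fu_amount: float,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
) -> ContributionReport:
    """Decompose gross impacts by stage label; stage rows sum to the total."""
    scales = process_scales(system, fu_amount)
    rows: dict[str, np.ndarray] = {}
    for proc in system.processes:
        vec = process_impacts(proc, scales[proc.id], background, cfs).as_array()
        rows[proc.stage_label] = rows.get(proc.stage_label, np.zeros(len(CATEGORIES))) + vec
    absolute = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    totals = absolute.sum(axis=0)
    denom = totals.replace(0.0, np.nan)
    shares = (absolute / denom).fillna(0.0)
    return ContributionReport(
        absolute=absolute, shares=shares, total=ImpactVector.from_array(totals.to_numpy())
    )


def matrix_solve_oracle(
    system: ProductSystem,
    fu_amount: float,
    background: BackgroundIntensityTable,
    cfs: CharacterizationTable,
) -> ImpactVector:
    """Independent evaluation through the square technology matrix.

    A[i, i] = primary output of process i; A[i, j] = -amount of i's
    primary product consumed per unit activity of process j.  Solving
    A s = f for the final-demand vector f gives the activity levels,
    which are then characterized process by process.  Must agree with
    :func:`compute_impacts` on any valid acyclic system.
    """
    procs = system.processes
    n = len(procs)
    idx = {p.id: i for i, p in enumerate(procs)}
    a = np.zeros((n, n))
    for j, proc in enumerate(procs):
        _, amt = proc.primary_output
        a[idx[proc.id], j] = amt
        for supplier_id, amount in proc.foreground_inputs:
            a[idx[supplier_id], j] -= amount
    f = np.zeros(n)
    ref = system.reference_process()
    f[idx[ref.id]] = fu_amount
    try:
        s = np.linalg.solve(a, f)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - constructed misuse
        raise ValueError(f"singular technology matrix: {exc}") from exc
    total = np.zeros(len(CATEGORIES))
    for j, proc in enumerate(procs):
        total += process_impacts(proc, s[j], background, cfs).as_array()
    return ImpactVector.from_array(total)
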