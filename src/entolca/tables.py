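"""Tabular containers: background intensities and characterization factors.

Both are thin, validated wrappers around a pandas DataFrame whose index
is the product (or elementary-flow) name and whose columns are the six
impact-category codes.  The background table is the stand-in for an
aggregated LCI database: one impact vector per unit of each purchased
product or energy flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CATEGORIES, ImpactVector

__all__ = ["BackgroundIntensityTable", "CharacterizationTable"]


def _validated_frame(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    missing = [c for c in CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing impact-category columns: {missing}")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate entries in {kind} table: {dups}")
    if list(df.columns) == list(CATEGORIES) and all(
        np.issubdtype(dt, np.floating) for dt in df.dtypes
    ):
        out = df  # already canonical; keep the caller's (possibly viewing) frame
    else:
        out = df.loc[:, list(CATEGORIES)].astype(float)
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)].tolist()
        raise ValueError(f"missing cells in {kind} table for: {bad}")
    return out


@dataclass
class BackgroundIntensityTable:
    """Per-unit impact vectors for purchased products and energy flows.

    ``units`` maps each product to its reference unit (kg, kWh, L,
    km·kg, m2, ...); intensities are per one such unit.
    """

    frame: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _validated_frame(self.frame, "background intensity")

    @classmethod
    def from_dict(
        cls, intensities: dict[str, dict[str, float]], units: dict[str, str] | None = None
    ) -> "BackgroundIntensityTable":
        df = pd.DataFrame.from_dict(intensities, orient="index").reindex(
            columns=list(CATEGORIES), fill_value=0.0
        ).fillna(0.0)
        return cls(frame=df, units=dict(units or {}))

    @classmethod
    def zeros(cls, products: list[str]) -> "BackgroundIntensityTable":
        return cls(frame=pd.DataFrame(0.0, index=pd.Index(products), columns=list(CATEGORIES)))

    def __contains__(self, product: str) -> bool:
        return product in self.frame.index

    @property
    def products(self) -> list[str]:
        return list(self.frame.index)

    def intensity(self, product: str) -> ImpactVector:
        if product not in self.frame.index:
            raise KeyError(f"no background intensity for product {product!r}")
        return ImpactVector.from_array(self.frame.loc[product].to_numpy())

    def scaled(self, factors: pd.DataFrame | float) -> "BackgroundIntensityTable":
        """Return a new table with intensities multiplied element-wise."""
        return BackgroundIntensityTable(frame=self.frame * factors, units=dict(self.units))

    def copy(self) -> "BackgroundIntensityTable":
        return BackgroundIntensityTable(frame=self.frame.copy(), units=dict(self.units))

    def equals(self, other: "BackgroundIntensityTable", rtol: float = 0.0) -> bool:
        if set(self.frame.index) != set(other.frame.index):
            return False
        a = self.frame.sort_index().to_numpy()
        b = other.frame.sort_index().to_numpy()
        return bool(np.allclose(a, b, rtol=rtol, atol=0.0))


@dataclass
class CharacterizationTable:
    """Impact vector per kg of each elementary flow (direct emission).

    Every emission named by any foreground process must have an entry;
    an all-zero row is a legitimate way to say "not characterized".
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _validated_frame(self.frame, "characterization")

    @classmethod
    def from_dict(cls, cfs: dict[str, dict[str, float]]) -> "CharacterizationTable":
        df = pd.DataFrame.from_dict(cfs, orient="index").reindex(
            columns=list(CATEGORIES), fill_value=0.0
        ).fillna(0.0)
        return cls(frame=df)

    @classmethod
    def zeros(cls, flows: list[str]) -> "CharacterizationTable":
        return cls(frame=pd.DataFrame(0.0, index=pd.Index(flows), columns=list(CATEGORIES)))

    def __contains__(self, flow: str) -> bool:
        return flow in self.frame.index

    def factor(self, flow: str) -> ImpactVector:
        if flow not in self.frame.index:
            raise KeyError(f"no characterization factors for emission {flow!r}")
        return ImpactVector.from_array(self.frame.loc[flow].to_numpy())


#: Characterization factors shipped with the fixtures for the three
#: rearing emissions: N2O at its 100-year global-warming potential,
#: fossil/biogenic CO2 at 1, and NH3 contributing to marine
#: eutrophication via its nitrogen content.  A stand-in table, not a
#: regulatory method.
DEFAULT_CFS = CharacterizationTable.from_dict(
    {
        "N2O": {"GWP": 273.0},
        "CO2": {"GWP": 1.0},
        "NH3": {"MEP": 0.0924},
    }
)
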