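"""Normalized connectivity quantification for retrograde tracing.

Monosynaptic rabies tracing yields, per brain, a count of presynaptic
neurons in each registered region and a count of the starter neurons the
trans-synaptic spread originated from.  The index of connectivity (IOC)
normalizes the former by the latter:

    IOC(region) = presynaptic neurons in region / starter neurons

making brains with different infection efficiency comparable.  Region
ratios (e.g. VPM/POm thalamus) summarise the balance of whisker-specific
vs multi-whisker thalamic input.  CTB double-labeling is summarised as the
percentage of retrogradely labeled transfected neurons and as labeled-cell
densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionCountTable",
    "IocTable",
    "compute_ioc",
    "ioc_ratio",
    "double_label_percent",
]


@dataclass
class RegionCountTable:
    """Per-region presynaptic counts for one brain/hemisphere."""

    counts: dict[str, int]
    starter_count: int
    hemisphere: str = "ipsi"

    def __post_init__(self):
        for r, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {r!r} must be a non-negative integer")
        if self.starter_count < 0:
            raise ValueError("starter_count must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal: str | None = None) -> "RegionCountTable":
        """Build from a CSV-style table (region, presynaptic_count, starter_count)."""
        if animal is not None:
            df = df[df["animal"] == animal]
        starters = df["starter_count"].unique()
        if len(starters) != 1:
            raise ValueError("expected a single starter_count per table")
        return cls(
            counts=dict(zip(df["region"], df["presynaptic_count"].astype(int))),
            starter_count=int(starters[0]),
            hemisphere=str(df["hemisphere"].iloc[0]) if "hemisphere" in df else "ipsi",
        )


@dataclass
class IocTable:
    """Per-region index of connectivity."""

    ioc: dict[str, float]
    starter_count: int
    hemisphere: str = "ipsi"

    def as_series(self) -> pd.Series:
        return pd.Series(self.ioc, name="ioc")


def compute_ioc(table: RegionCountTable) -> IocTable:
    """Presynaptic count per region divided by the starter count."""
    if table.starter_count < 1:
        raise ValueError("IOC undefined for starter_count = 0")
    return IocTable(
        ioc={r: c / table.starter_count for r, c in table.counts.items()},
        starter_count=table.starter_count,
        hemisphere=table.hemisphere,
    )


def ioc_ratio(ioc: IocTable, numerator: str, denominator: str) -> float:
    """Ratio of two regions' IOC values (e.g. VPM/POm)."""
    for r in (numerator, denominator):
        if r not in ioc.ioc:
            raise KeyError(f"region {r!r} not present")
    den = ioc.ioc[denominator]
    if den == 0:
        warnings.warn(f"zero denominator IOC for {denominator!r}; ratio undefined")
        return np.nan
    return ioc.ioc[numerator] / den


def double_label_percent(counts: pd.DataFrame) -> pd.DataFrame:
    """Double-label percentage and labeled-cell density per section.

    Expects columns ``n_double`` (e.g. CTB+GFP+), ``n_transfected`` (GFP+),
    ``n_labeled`` (CTB+) and ``area`` (ROI area).  Returns the input plus
    ``percent = 100 * n_double / n_transfected`` and
    ``density = n_labeled / area``; rows with a zero denominator get NaN
    and a warning.
    """
    out = counts.copy()
    if (out["n_double"] > out["n_transfected"]).any():
        raise ValueError("n_double cannot exceed n_transfected")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["percent"] = np.where(
            out["n_transfected"] > 0,
            100.0 * out["n_double"] / out["n_transfected"], np.nan)
        out["density"] = np.where(out["area"] > 0, out["n_labeled"] / out["area"], np.nan)
    if out["percent"].isna().any() or out["density"].isna().any():
        warnings.warn("sections with zero denominators flagged as missing (NaN)")
    return out
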