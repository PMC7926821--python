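"""Absolute and relative regional mortality indicators.

Raw accident and death counts reflect exposure: populous, economically
developed provinces build more and therefore record more accidents.  The
relative indexes normalize the death toll by the construction sector's size:

* death rate per unit of production value = deaths / production value,
  production value in units of 10^11 CNY;
* death rate of staff = deaths / employees, employees in units of 10^5.

Both scale linearly in deaths and inversely in the denominator, so a province
with a small construction sector but an average death toll (e.g. Hainan or
Qinghai) can rank far worse on the relative indexes than on the raw counts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .registry import REGIONS

__all__ = [
    "death_rate_per_production",
    "death_rate_per_staff",
    "build_panel",
    "infer_denominators",
]

PANEL_COLUMNS = [
    "accidents",
    "deaths",
    "production_value_1e11cny",
    "employees_1e5",
    "rate_production",
    "rate_staff",
    "cluster_absolute",
    "cluster_relative",
]


def death_rate_per_production(deaths: float, production_value: float) -> float:
    """Deaths per 10^11 CNY of construction production value."""
    if production_value <= 0:
        raise ValueError(f"production value must be positive, got {production_value}")
    if deaths < 0:
        raise ValueError(f"deaths must be non-negative, got {deaths}")
    return deaths / production_value

def death_rate_per_staff(deaths: float, employees: float) -> float:
    """Deaths per 10^5 construction employees."""
    if employees <= 0:
        raise ValueError(f"employees must be positive, got {employees}")
    if deaths < 0:
        raise ValueError(f"deaths must be non-negative, got {deaths}")
    return deaths / employees


def build_panel(
    counts: Mapping[str, tuple[int, int]] | pd.DataFrame,
    production_value: Mapping[str, float] | None = None,
    employees: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble a province panel from per-region counts and denominators.

    ``counts`` maps region -> (accidents, deaths), or is a DataFrame with
    ``accidents``/``deaths`` columns indexed by region.  When denominators
    are supplied the two relative rates are computed; cluster columns start
    unset.  Regions must be unique and drawn from the closed 31-entry list.
    """
    if isinstance(counts, pd.DataFrame):
        regions = list(counts.index)
        acc = counts["accidents"].to_dict()
        dea = counts["deaths"].to_dict()
    else:
        regions = list(counts)
        acc = {r: counts[r][0] for r in regions}
        dea = {r: counts[r][1] for r in regions}

    dupes = {r for r in regions if regions.count(r) > 1}
    if dupes:
        raise ValueError(f"duplicate region(s): {sorted(dupes)}")
    unknown = [r for r in regions if r not in REGIONS]
    if unknown:
        raise ValueError(f"unknown region(s): {unknown}")

    df = pd.DataFrame(index=pd.Index(regions, name="region"), columns=PANEL_COLUMNS)
    df["accidents"] = [acc[r] for r in regions]
    df["deaths"] = [dea[r] for r in regions]
    if production_value is not None:
        missing = [r for r in regions if r not in production_value]
        if missing:
            raise ValueError(f"missing production value for: {missing}")
        df["production_value_1e11cny"] = [production_value[r] for r in regions]
        df["rate_production"] = [
            death_rate_per_production(dea[r], production_value[r]) for r in regions
        ]
    if employees is not None:
        missing = [r for r in regions if r not in employees]
        if missing:
            raise ValueError(f"missing employee count for: {missing}")
        df["employees_1e5"] = [employees[r] for r in regions]
        df["rate_staff"] = [death_rate_per_staff(dea[r], employees[r]) for r in regions]
    return df


def infer_denominators(panel: pd.DataFrame) -> pd.DataFrame:
    """Back-compute denominators from deaths and the printed rates.

    Surveillance reports often print the rates but not the underlying
    production values and employee counts.  Inverting ``rate = deaths /
    denominator`` recovers denominators that reproduce the printed rates by
    construction; the returned frame marks them ``inferred`` to keep them
    distinct from measured values.
    """
    out = panel.copy()
    with np.errstate(divide="ignore"):
        out["production_value_1e11cny"] = out["deaths"] / out["rate_production"]
        out["employees_1e5"] = out["deaths"] / out["rate_staff"]
    out["denominators_inferred"] = True
    return out
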