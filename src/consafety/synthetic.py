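"""Seeded generators for registries, province panels, and grey-model series.

The registry generator emulates the statistical structure a national
fatal-accident surveillance feed exhibits: yearly accident counts around a
trend (Poisson), monthly seasonality peaking in August (typhoon/heat season)
with a February trough (Spring Festival shutdown), mild weekday effects
(Sunday/Monday high, Tuesday low), a five-category accident-type
multinomial dominated by falls from height, region shares proportional to
the reference panel, and a heavy-tailed deaths-per-accident law in which
major accidents (>=3 deaths) are ~4.3% of events and severe ones (>=10)
~0.12%.  Every draw is recorded in a ledger so aggregations downstream can
be verified against exact bookkeeping.

The generator emulates categorical marginals only — no weather, holiday, or
spatial correlation mechanisms — so tests built on it validate counting,
classification, and model-fitting logic, not causal realism.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import REGIONS, AccidentRecord, AccidentType

__all__ = [
    "RegistryGeneratorParams",
    "GenerationLedger",
    "generate_registry",
    "generate_panel",
    "generate_gm_series",
    "DEATHS_GEOMETRIC_P",
    "SEVERE_WEIGHT",
]

# Deaths-per-accident law: zero-truncated geometric on {1, 2, ...} mixed with
# a small uniform{10..29} severe component.  The severe weight matches the
# observed severe share (~7 in 6005); the geometric decay q solves
# (1 - w) q^2 + w = 0.043 so that the major+severe share is 4.3% exactly.
SEVERE_WEIGHT = 0.0012
_Q = float(np.sqrt((0.043 - SEVERE_WEIGHT) / (1.0 - SEVERE_WEIGHT)))
DEATHS_GEOMETRIC_P = 1.0 - _Q

# Default month weights (Jan..Dec): August peak, February trough, secondary
# July/November highs — ordinal pattern only, magnitudes are conventional.
_MONTH_WEIGHTS = (1.0, 0.70, 0.95, 1.0, 1.05, 1.05, 1.20, 1.30, 1.05, 1.10, 1.20, 0.95)
# Default ISO-weekday weights (Mon..Sun): Monday/Sunday high, Tuesday low.
_WEEKDAY_WEIGHTS = (1.20, 0.80, 1.0, 1.05, 1.0, 0.85, 1.25)
# Type shares: falls ~51.66%, struck-by ~14.15%, collapse ~11.76%,
# lifting ~8.18%, other ~14.25%.
_TYPE_PROBS = (0.5166, 0.1415, 0.1176, 0.0818, 0.1425)


def _default_region_probs() -> np.ndarray:
    from .datasets import load_province_panel

    acc = load_province_panel()["accidents"].reindex(list(REGIONS)).to_numpy(float)
    return acc / acc.sum()


@dataclass
class RegistryGeneratorParams:
    """Study conditions for the registry generator.

    ``mean_accidents_per_year`` is the Poisson mean in the first year;
    ``annual_trend`` is a multiplicative growth factor applied per year
    (0.0 = flat).  Weight vectors need not be normalized, only positive.
    """

    years: range = field(default_factory=lambda: range(2010, 2020))
    mean_accidents_per_year: float = 600.0
    annual_trend: float = 0.0
    month_weights: tuple = _MONTH_WEIGHTS
    weekday_weights: tuple = _WEEKDAY_WEIGHTS
    type_probs: tuple = _TYPE_PROBS
    region_probs: tuple | None = None
    deaths_geometric_p: float = DEATHS_GEOMETRIC_P
    severe_weight: float = SEVERE_WEIGHT

    def __post_init__(self) -> None:
        if len(self.years) == 0:
            raise ValueError("years range is empty")
        if self.mean_accidents_per_year <= 0:
            raise ValueError("mean accidents per year must be positive")
        for name, w, m in [
            ("month_weights", self.month_weights, 12),
            ("weekday_weights", self.weekday_weights, 7),
            ("type_probs", self.type_probs, 5),
        ]:
            if len(w) != m or any(v <= 0 for v in w):
                raise ValueError(f"{name} must be {m} positive values")
        if self.region_probs is not None:
            rp = np.asarray(self.region_probs, float)
            if len(rp) != len(REGIONS) or (rp <= 0).any():
                raise ValueError("region_probs must be 31 positive values")
            if abs(rp.sum() - 1.0) > 1e-9:
                raise ValueError("region_probs must sum to 1")
        if not 0 < self.deaths_geometric_p < 1:
            raise ValueError("deaths_geometric_p must lie in (0, 1)")
        if not 0 <= self.severe_weight < 1:
            raise ValueError("severe_weight must lie in [0, 1)")


@dataclass
class GenerationLedger:
    """Exact bookkeeping of every draw the generator made.

    ``draws`` has one row per generated record (year, month, weekday, date,
    region, accident_type, deaths); ``year_counts`` are the Poisson draws.
    Aggregations over the emitted records must recount this ledger exactly.
    """

    year_counts: dict[int, int]
    draws: pd.DataFrame

    def recount(self, column: str) -> pd.Series:
        return self.draws.groupby(column).size()


def _day_table(year: int, month_w, weekday_w) -> tuple[np.ndarray, np.ndarray]:
    """All days of a year with weight month_w[m] * weekday_w[iso_wd]."""
    start = dt.date(year, 1, 1)
    n_days = 366 if calendar.isleap(year) else 365
    days = np.array([start + dt.timedelta(days=i) for i in range(n_days)])
    w = np.array([month_w[d.month - 1] * weekday_w[d.isoweekday() - 1] for d in days])
    return days, w / w.sum()


def _draw_deaths(rng: np.random.Generator, n: int, p: float, severe_w: float) -> np.ndarray:
    deaths = rng.geometric(p, size=n)            # zero-truncated: support {1,2,...}
    severe = rng.random(n) < severe_w
    deaths[severe] = rng.integers(10, 30, size=severe.sum())
    return deaths


def generate_registry(
    params: RegistryGeneratorParams | None = None,
    seed: int | None = 0,
) -> tuple[list[AccidentRecord], GenerationLedger]:
    """Draw a synthetic accident registry under the given study conditions.

    Yearly counts are Poisson around the (possibly trending) mean; each
    accident independently draws a calendar day (weighted by month and
    weekday), a region, a type, and a death toll.  Identical seeds yield
    identical registries.
    """
    params = params or RegistryGeneratorParams()
    rng = np.random.default_rng(seed)
    region_probs = (
        np.asarray(params.region_probs, float)
        if params.region_probs is not None
        else _default_region_probs()
    )
    type_values = list(AccidentType)

    records: list[AccidentRecord] = []
    rows = []
    year_counts: dict[int, int] = {}
    y0 = params.years[0]
    for year in params.years:
        mean = params.mean_accidents_per_year * (1.0 + params.annual_trend) ** (year - y0)
        n = int(rng.poisson(mean))
        year_counts[year] = n
        if n == 0:
            continue
        days, day_p = _day_table(year, params.month_weights, params.weekday_weights)
        dates = days[rng.choice(len(days), size=n, p=day_p)]
        regions = rng.choice(len(REGIONS), size=n, p=region_probs)
        types = rng.choice(5, size=n, p=np.asarray(params.type_probs) / sum(params.type_probs))
        deaths = _draw_deaths(rng, n, params.deaths_geometric_p, params.severe_weight)
        for d, reg, ty, k in zip(dates, regions, types, deaths):
            rec = AccidentRecord(
                date=d,
                region=REGIONS[reg],
                deaths=int(k),
                accident_type=type_values[ty],
            )
            records.append(rec)
            rows.append(
                (d.year, d.month, d.isoweekday(), d, rec.region,
                 rec.accident_type.value, rec.deaths)
            )

    draws = pd.DataFrame(
        rows, columns=["year", "month", "weekday", "date", "region",
                       "accident_type", "deaths"],
    )
    return records, GenerationLedger(year_counts, draws)


def generate_panel(
    base: pd.DataFrame,
    perturbation_scale: float,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Multiplicatively jitter a province panel.

    Counts and rate columns are multiplied by independent lognormal factors
    exp(N(0, scale)); counts are re-rounded to integers (floor 1 so no region
    vanishes).  Scale 0 returns the base panel verbatim.
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation scale must be non-negative")
    out = base.copy()
    if perturbation_scale == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in ("accidents", "deaths"):
        jitter = np.exp(rng.normal(0.0, perturbation_scale, len(out)))
        out[col] = np.maximum(1, np.rint(out[col].to_numpy(float) * jitter)).astype(int)
    for col in ("rate_production", "rate_staff"):
        if col in out:
            jitter = np.exp(rng.normal(0.0, perturbation_scale, len(out)))
            out[col] = out[col].to_numpy(float) * jitter
    return out


def generate_gm_series(
    a: float,
    b: float,
    x1: float,
    n: int,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Emit a series following the GM(1,1) restored-series recursion.

    x(1) = x1 and x(k+1) = (1 - e^a)(x1 - b/a) e^(-a k), each value
    multiplied by lognormal noise exp(N(0, noise_sd)).  With a = 0 the
    exact trajectory is the constant-series limit (all values b).
    ``noise_sd = 0`` gives the exact trajectory, which refits to the same
    (a, b).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if x1 <= 0:
        raise ValueError("x1 must be positive")
    k = np.arange(1, n)
    if a == 0:
        tail = np.full(n - 1, float(b))
    else:
        tail = (1.0 - np.exp(a)) * (x1 - b / a) * np.exp(-a * k)
    x = np.concatenate([[float(x1)], tail])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x * np.exp(rng.normal(0.0, noise_sd, n))
    return x
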