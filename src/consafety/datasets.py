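"""Loaders for the small reference tables shipped with the package.

Three plain-CSV fixtures are bundled: the 10-year national deaths series
(2010-2019), the 31-region province panel with printed mortality rates and
cluster labels, and the list of the seven severe accidents of the decade.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .registry import AccidentRecord, read_registry

__all__ = ["load_deaths_series", "load_province_panel", "load_severe_accidents"]


def _path(name: str):
    return resources.files("consafety.data").joinpath(name)


def load_deaths_series() -> pd.Series:
    """Annual construction deaths 2010-2019 as a Series indexed by year."""
    with resources.as_file(_path("national_deaths.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("year")["deaths"]


def load_province_panel() -> pd.DataFrame:
    """31-region panel: accident/death counts, the two relative mortality
    rates (deaths per 10^11 CNY production value; deaths per 10^5 employees),
    and the reference cluster labels for the absolute and relative factors.
    Indexed by region."""
    with resources.as_file(_path("province_panel.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("region")


def load_severe_accidents() -> list[AccidentRecord]:
    """The seven severe accidents (>=10 deaths) of 2010-2019 as records."""
    with resources.as_file(_path("severe_accidents.csv")) as p:
        return read_registry(str(p))
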