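"""Accident registry: data model, CSV I/O, severity classification, aggregation.

A registry is a collection of per-accident records from an occupational
fatality surveillance system: each record carries the calendar date, the
province or municipality, the accident type, the site location (where
recorded), the death toll, and a serious-injury flag.  Severity follows the
Chinese State Council Order No. 493 bands, which are keyed on the number of
deaths alone.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "REGIONS",
    "AccidentType",
    "LocationCategory",
    "SeverityLevel",
    "AccidentRecord",
    "FrequencyTable",
    "SummaryRatios",
    "RegistryError",
    "RowError",
    "classify_severity",
    "read_registry",
    "write_registry",
    "aggregate",
    "summary_ratios",
    "round_half_up",
]

#: Closed list of the 31 mainland provinces, municipalities, and autonomous
#: regions (Hong Kong, Macao, and Taiwan excluded), in conventional order.
REGIONS: tuple[str, ...] = (
    "Beijing", "Tianjin", "Hebei", "Shanxi", "Inner Mongolia",
    "Liaoning", "Jilin", "Heilongjiang",
    "Shanghai", "Jiangsu", "Zhejiang", "Anhui", "Fujian", "Jiangxi", "Shandong",
    "Henan", "Hubei", "Hunan", "Guangdong", "Guangxi", "Hainan",
    "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Xizang",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)


class AccidentType(str, enum.Enum):
    """Accident categories per GB6441-86; ``other`` pools the minor types
    (mechanical injury, fire/explosion, poisoning, vehicle injury, drowning,
    electric shock)."""

    fall_from_height = "fall_from_height"
    struck_by_object = "struck_by_object"
    collapse = "collapse"
    lifting_injury = "lifting_injury"
    other = "other"


class LocationCategory(str, enum.Enum):
    """Site-location categories; only recorded in early surveillance years."""

    openings_and_edges = "openings_and_edges"
    scaffold = "scaffold"
    tower_crane = "tower_crane"
    other = "other"


class SeverityLevel(enum.IntEnum):
    """Ordered severity bands on the death toll: [0,3), [3,10), [10,30), >=30."""

    ordinary = 1
    major = 2
    severe = 3
    extraordinarily_severe = 4


class RegistryError(ValueError):
    """Raised for malformed registry input."""


@dataclass(frozen=True)
class RowError:
    """A rejected CSV row: 1-based data-row index plus a reason."""

    row: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.message}"


@dataclass
class AccidentRecord:
    """One fatal accident.

    ``accident_type`` and ``location`` are optional because the surveillance
    source omits them for some years (no types in 2013; no locations after
    2011).  ``deaths`` must be non-negative; ``region`` must belong to the
    closed 31-entry list.
    """

    date: dt.date
    region: str
    deaths: int
    accident_type: AccidentType | None = None
    location: LocationCategory | None = None
    serious_injury: bool = False

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise RegistryError(f"deaths must be non-negative, got {self.deaths}")
        if self.region not in REGIONS:
            raise RegistryError(f"unknown region {self.region!r}")

    @property
    def severity(self) -> SeverityLevel:
        return classify_severity(self.deaths, self.serious_injury)

    @property
    def weekday(self) -> int:
        """ISO weekday, Monday = 1 .. Sunday = 7."""
        return self.date.isoweekday()


def classify_severity(deaths: int, serious_injury: bool = False) -> SeverityLevel:
    """Map a death toll to its severity band.

    The bands partition the non-negative integers: [0,3) ordinary, [3,10)
    major, [10,30) severe, >=30 extraordinarily severe.  The serious-injury
    flag only characterizes the ordinary floor (an event with no deaths but
    serious injuries still counts as an ordinary *fatal-register* accident);
    it never escalates the band, which is keyed on deaths alone.
    """
    if deaths < 0:
        raise RegistryError(f"deaths must be non-negative, got {deaths}")
    if deaths < 3:
        return SeverityLevel.ordinary
    if deaths < 10:
        return SeverityLevel.major
    if deaths < 30:
        return SeverityLevel.severe
    return SeverityLevel.extraordinarily_severe


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("date", "region", "accident_type", "location", "deaths", "serious_injury")
_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_row(
    row: dict[str, str],
    lenient: bool,
    window: tuple[dt.date, dt.date] | None,
) -> AccidentRecord:
    try:
        date = dt.date.fromisoformat(row["date"].strip())
    except ValueError as exc:
        raise RegistryError(f"malformed date {row['date']!r}: {exc}") from None
    if window is not None and not (window[0] <= date <= window[1]):
        raise RegistryError(f"date {date} outside study window {window[0]}..{window[1]}")

    region = row["region"].strip()
    if region not in REGIONS:
        raise RegistryError(f"unknown region {region!r}")

    raw_type = (row.get("accident_type") or "").strip()
    if not raw_type:
        accident_type = None
    else:
        try:
            accident_type = AccidentType(raw_type)
        except ValueError:
            if lenient:
                accident_type = AccidentType.other
            else:
                raise RegistryError(f"unknown accident_type {raw_type!r}") from None

    raw_loc = (row.get("location") or "").strip()
    if not raw_loc:
        location = None
    else:
        try:
            location = LocationCategory(raw_loc)
        except ValueError:
            if lenient:
                location = LocationCategory.other
            else:
                raise RegistryError(f"unknown location {raw_loc!r}") from None

    try:
        deaths = int(row["deaths"])
    except ValueError:
        raise RegistryError(f"malformed deaths {row['deaths']!r}") from None
    if deaths < 0:
        raise RegistryError(f"negative deaths {deaths}")

    flag = (row.get("serious_injury") or "").strip().lower()
    if flag in _TRUE:
        serious = True
    elif flag in _FALSE:
        serious = False
    else:
        raise RegistryError(f"malformed serious_injury {row['serious_injury']!r}")

    return AccidentRecord(date, region, deaths, accident_type, location, serious)


def read_registry(
    source: str | TextIO,
    *,
    lenient: bool = False,
    study_window: tuple[dt.date, dt.date] | None = None,
    errors: str = "raise",
) -> list[AccidentRecord] | tuple[list[AccidentRecord], list[RowError]]:
    """Parse a registry CSV into :class:`AccidentRecord` objects.

    Parameters
    ----------
    source:
        Path or open text stream.  The header must contain the documented
        columns ``date, region, accident_type, location, deaths,
        serious_injury``; extra columns are ignored.
    lenient:
        Map unknown ``accident_type``/``location`` labels to ``other``
        instead of rejecting the row.  Unknown regions are always rejected.
    study_window:
        Optional inclusive ``(start, end)`` date range; out-of-window rows
        are rejected.
    errors:
        ``"raise"`` (default) raises :class:`RegistryError` listing every bad
        row; ``"collect"`` returns ``(records, row_errors)`` instead.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")

    if isinstance(source, (str,)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_registry(
                fh, lenient=lenient, study_window=study_window, errors=errors
            )

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise RegistryError("empty registry file (no header)")
    missing = [c for c in _COLUMNS if c not in reader.fieldnames]
    if missing:
        raise RegistryError(f"missing required columns: {', '.join(missing)}")

    records: list[AccidentRecord] = []
    row_errors: list[RowError] = []
    n_rows = 0
    for i, row in enumerate(reader, start=1):
        n_rows += 1
        try:
            records.append(_parse_row(row, lenient, study_window))
        except RegistryError as exc:
            row_errors.append(RowError(i, str(exc)))
    if n_rows == 0:
        raise RegistryError("empty registry file (header but no rows)")

    if errors == "collect":
        return records, row_errors
    if row_errors:
        detail = "; ".join(str(e) for e in row_errors[:10])
        raise RegistryError(f"{len(row_errors)} bad row(s): {detail}")
    return records


def write_registry(records: Iterable[AccidentRecord], dest: str | TextIO) -> None:
    """Write records in the documented CSV dialect (inverse of read_registry)."""
    if isinstance(dest, str):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_registry(records, fh)
            return
    writer = csv.writer(dest)
    writer.writerow(_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.date.isoformat(),
                r.region,
                r.accident_type.value if r.accident_type else "",
                r.location.value if r.location else "",
                r.deaths,
                "true" if r.serious_injury else "false",
            ]
        )


def registry_to_csv(records: Iterable[AccidentRecord]) -> str:
    buf = io.StringIO()
    write_registry(records, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

#: Supported grouping keys and how each value is derived from a record.
_KEY_FUNCS = {
    "year": lambda r: r.date.year,
    "month": lambda r: r.date.month,
    "weekday": lambda r: r.weekday,
    "accident_type": lambda r: r.accident_type.value if r.accident_type else None,
    "location": lambda r: r.location.value if r.location else None,
    "region": lambda r: r.region,
    "severity": lambda r: r.severity.name,
}


@dataclass
class FrequencyTable:
    """Per-group accident and death counts with percentages.

    ``table`` is indexed by group value with columns ``accidents``,
    ``deaths``, ``pct_accidents``, ``pct_deaths``.  Percentages use
    ``n_annotated`` (records carrying the grouping attribute) as the base;
    for complete keys this equals ``n_records``, the post-filter total.
    """

    key: str
    table: pd.DataFrame
    n_records: int
    n_annotated: int

    def to_csv(self, dest: str | TextIO) -> None:
        self.table.rename_axis("group").to_csv(dest)

    def to_json(self) -> str:
        return self.table.rename_axis("group").reset_index().to_json(orient="records")


def _group_domain(key: str, records: Sequence[AccidentRecord]) -> list:
    if key == "month":
        return list(range(1, 13))
    if key == "weekday":
        return list(range(1, 8))
    if key == "accident_type":
        return [t.value for t in AccidentType]
    if key == "location":
        return [loc.value for loc in LocationCategory]
    if key == "region":
        return list(REGIONS)
    if key == "severity":
        return [s.name for s in SeverityLevel]
    # year: observed span, so zero-count years inside it are reported
    years = [r.date.year for r in records]
    return list(range(min(years), max(years) + 1)) if years else []


def aggregate(
    records: Sequence[AccidentRecord],
    key: str,
    severity_filter: Iterable[SeverityLevel] | None = None,
) -> FrequencyTable:
    """Count accidents and deaths per group of ``key``.

    Zero-event groups are retained with count 0.  Percentages are computed
    against the filtered (and, for ``accident_type``, annotated-subset)
    totals, so they sum to 100 within rounding whenever any events remain.

    An empty selection yields an all-zero table rather than an error.  A
    ``location`` aggregation refuses a registry that mixes location-annotated
    and non-annotated records — location data only exist for the early study
    years, and mixing the two would silently bias the percentages; filter to
    the annotated years first.
    """
    if key not in _KEY_FUNCS:
        raise ValueError(f"unsupported grouping key {key!r}; choose from {sorted(_KEY_FUNCS)}")

    if severity_filter is not None:
        allowed = set(severity_filter)
        selected = [r for r in records if r.severity in allowed]
    else:
        selected = list(records)

    fn = _KEY_FUNCS[key]
    values = [fn(r) for r in selected]
    if key == "location" and selected:
        n_missing = sum(v is None for v in values)
        if 0 < n_missing < len(values):
            raise RegistryError(
                "registry mixes location-annotated and non-annotated records; "
                "filter to the location-annotated years before aggregating by location"
            )
    annotated = [(v, r) for v, r in zip(values, selected) if v is not None]

    domain = _group_domain(key, selected)
    acc = {g: 0 for g in domain}
    dea = {g: 0 for g in domain}
    for v, r in annotated:
        acc[v] = acc.get(v, 0) + 1
        dea[v] = dea.get(v, 0) + r.deaths

    table = pd.DataFrame(
        {"accidents": pd.Series(acc), "deaths": pd.Series(dea)}
    ).loc[list(acc)]
    tot_acc = table["accidents"].sum()
    tot_dea = table["deaths"].sum()
    table["pct_accidents"] = 100.0 * table["accidents"] / tot_acc if tot_acc else 0.0
    table["pct_deaths"] = 100.0 * table["deaths"] / tot_dea if tot_dea else 0.0
    return FrequencyTable(
        key=key, table=table, n_records=len(selected), n_annotated=len(annotated)
    )


# ---------------------------------------------------------------------------
# Summary ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryRatios:
    deaths_per_accident: float | None
    deaths_per_day: float
    n_days: int


def summary_ratios(
    total_accidents: int,
    total_deaths: int,
    window: tuple[dt.date, dt.date],
) -> SummaryRatios:
    """Deaths per accident and deaths per calendar day over an inclusive window.

    The day count includes both endpoints and counts leap days, so the
    2010-01-01..2019-12-31 decade spans 3652 days.  With zero accidents the
    per-accident ratio is undefined and returned as ``None``.
    """
    start, end = window
    n_days = (end - start).days + 1
    if n_days <= 0:
        raise ValueError("window must span at least one day")
    dpa = total_deaths / total_accidents if total_accidents > 0 else None
    return SummaryRatios(dpa, total_deaths / n_days, n_days)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report display rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
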