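"""Survey data model: records, CSV ingestion, exclusion filters and tabulations.

One row of a field survey is a single mussel observation: which oxbow lake it
came from, the year, the day of the spawning season (counted from 1 May), the
host species, and whether bitterling embryos were released from it while it was
held in a mesh bag. Months are derived from season-day when no calendar date is
available (May = days 1-31, June = 32-61, July = 62-92, August = 93+).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError

SPECIES = ("anatina", "cygnea", "pictorum", "tumidus")
MONTHS = ("May", "June", "July", "August")

#: canonical CSV columns; `date`, `release_count`, `depth_mm`, `length_mm` optional
REQUIRED_COLUMNS = ("lake", "year", "day", "species", "released")
OPTIONAL_COLUMNS = ("date", "release_count", "depth_mm", "length_mm")

DAY_MIN, DAY_MAX = 1, 123  # 1 May .. 31 Aug


def month_from_day(day: int) -> str:
    """Map a day-since-1-May to its month (fallback when no calendar date)."""
    if day < DAY_MIN or day > DAY_MAX:
        raise ValidationError(f"day {day} outside season range {DAY_MIN}-{DAY_MAX}")
    if day <= 31:
        return "May"
    if day <= 61:
        return "June"
    if day <= 92:
        return "July"
    return "August"


@dataclass(frozen=True)
class SurveyRecord:
    """A single mussel observation."""

    lake_id: int
    year: int
    day: int
    species: str
    released: int
    month: str = field(default="")
    release_count: int | None = None
    depth_mm: int | None = None
    length_mm: float | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r}; admissible: {SPECIES}"
            )
        if self.released not in (0, 1):
            raise ValidationError(f"released must be 0/1, got {self.released!r}")
        if self.month == "":
            object.__setattr__(self, "month", month_from_day(self.day))
        elif self.month not in MONTHS:
            raise ValidationError(f"unknown month {self.month!r}")
        else:
            month_from_day(self.day)  # still range-check the day
        if self.release_count is not None:
            if self.release_count < 0:
                raise ValidationError("release_count must be nonnegative")
            if self.released != int(self.release_count > 0):
                raise ValidationError(
                    "released must equal (release_count > 0) when a count is given"
                )


def _coerce_int(value, what, row):
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {what} not an integer: {value!r}")


def read_survey(path, dialect: Mapping[str, str] | None = None) -> list[SurveyRecord]:
    """Read survey records from a CSV file.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    dialect : mapping, optional
        Maps canonical column names (``lake``, ``year``, ``day``, ``species``,
        ``released``, and optionally ``date``, ``release_count``, ``depth_mm``,
        ``length_mm``) to the column names actually present in the file.

    Raises
    ------
    ConfigError
        if a required column is absent.
    ValidationError
        listing the offending row numbers, if any row is malformed.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    for canon in REQUIRED_COLUMNS:
        if colmap[canon] not in frame.columns:
            raise ConfigError(
                f"required column {colmap[canon]!r} (for {canon!r}) missing from {path}"
            )

    records: list[SurveyRecord] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        row = dict(zip(frame.columns, row))
        try:
            day = _coerce_int(row[colmap["day"]], "day", i)
            month = ""
            datecol = colmap["date"]
            if datecol in frame.columns and row[datecol].strip():
                ts = pd.Timestamp(row[datecol])
                month = ts.month_name()
                if month not in MONTHS:
                    raise ValidationError(f"row {i}: date {row[datecol]!r} outside May-August")
            kwargs = {}
            for opt, caster in (("release_count", int), ("depth_mm", int), ("length_mm", float)):
                col = colmap[opt]
                if col in frame.columns and str(row[col]).strip():
                    kwargs[opt] = caster(row[col])
            records.append(
                SurveyRecord(
                    lake_id=_coerce_int(row[colmap["lake"]], "lake", i),
                    year=_coerce_int(row[colmap["year"]], "year", i),
                    day=day,
                    species=str(row[colmap["species"]]).strip().lower(),
                    released=_coerce_int(row[colmap["released"]], "released", i),
                    month=month,
                    **kwargs,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError("malformed rows:\n" + "\n".join(problems))
    return records


def write_survey(records: Iterable[SurveyRecord], path) -> None:
    """Write records to CSV in the canonical dialect (round-trips read_survey).

    ``path`` may be a filesystem path or any writable text stream.
    """
    cols = ["lake", "year", "day", "species", "released",
            "release_count", "depth_mm", "length_mm"]
    import contextlib
    ctx = (contextlib.nullcontext(path) if hasattr(path, "write")
           else open(path, "w", newline=""))
    with ctx as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.lake_id, r.year, r.day, r.species, r.released,
                "" if r.release_count is None else r.release_count,
                "" if r.depth_mm is None else r.depth_mm,
                "" if r.length_mm is None else r.length_mm,
            ])


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Records as a DataFrame (one column per SurveyRecord field)."""
    names = [f.name for f in fields(SurveyRecord)]
    return pd.DataFrame([{n: getattr(r, n) for n in names} for r in records])


def apply_exclusions(
    records: Sequence[SurveyRecord],
    excluded_lakes: Iterable[int] = (),
    excluded_months: Iterable[str] = (),
) -> list[SurveyRecord]:
    """Drop records from excluded lakes or months, preserving order.

    The survey analysis excludes August (no embryo releases were observed then)
    and two lakes with incomplete species/month coverage.
    """
    lakes = frozenset(excluded_lakes)
    months = frozenset(excluded_months)
    return [r for r in records if r.lake_id not in lakes and r.month not in months]


_AXES = {
    "lake": lambda r: r.lake_id,
    "month": lambda r: r.month,
    "year": lambda r: r.year,
    "species": lambda r: r.species,
}

_AXIS_ORDER = {
    "month": list(MONTHS),
    "species": list(SPECIES),
}


@dataclass
class CountTable:
    """Cross-tabulation of survey records with margin totals."""

    table: pd.DataFrame  # rows x cols of counts
    row_totals: pd.Series
    col_totals: pd.Series
    grand_total: int


def tabulate(records: Sequence[SurveyRecord], rows: str, cols: str | None = None) -> CountTable:
    """Cross-tabulate records along one or two of {lake, month, year, species}."""
    for axis in (rows, cols):
        if axis is not None and axis not in _AXES:
            raise ConfigError(f"unknown axis {axis!r}; choose from {sorted(_AXES)}")
    rkeys = [_AXES[rows](r) for r in records]
    if cols is None:
        counted = pd.Series(rkeys).value_counts() if records else pd.Series(dtype=int)
        order = _AXIS_ORDER.get(rows)
        if order is not None:
            counted = counted.reindex(order, fill_value=0)
        else:
            counted = counted.sort_index()
        frame = counted.to_frame(name="count").astype(int)
        return CountTable(frame, frame["count"], pd.Series({"count": int(frame["count"].sum())}),
                          int(frame["count"].sum()))
    ckeys = [_AXES[cols](r) for r in records]
    frame = pd.crosstab(pd.Series(rkeys, name=rows), pd.Series(ckeys, name=cols))
    for axis_name, axis_idx in ((rows, 0), (cols, 1)):
        order = _AXIS_ORDER.get(axis_name)
        if order is not None:
            frame = frame.reindex(order, axis=axis_idx, fill_value=0)
    frame = frame.fillna(0).astype(int)
    return CountTable(frame, frame.sum(axis=1), frame.sum(axis=0), int(frame.values.sum()))
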