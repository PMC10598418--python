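"""Trossa-level fishing records: domain types, validation and delimited-table I/O.

A *trossa* is a tier of bottom-set gillnets tied together, set on the seabed
and hauled after a soak of (legally) up to three days.  It is the unit of
fishing effort in the Icelandic lumpfish fishery: one row of the study table
corresponds to one trossa set and hauled once, with its geometry (net length,
number of nets, net height), set depth, a flag marking whether a looming-eyes
buoy (LEB) deterrent was attached, and the counts of lumpfish, seabirds and
marine mammals it caught.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .errors import RowParseError, SchemaError

logger = logging.getLogger(__name__)

#: Bird species recorded in the 2022 Icelandic trial, used as the default
#: species columns of the table dialect.
BIRD_SPECIES = (
    "black_guillemot",
    "common_guillemot",
    "atlantic_puffin",
    "european_shag",
    "great_cormorant",
    "common_eider",
    "long_tailed_duck",
    "red_throated_diver",
    "northern_fulmar",
)

MAMMAL_SPECIES = (
    "harbour_seal",
    "grey_seal",
    "harp_seal",
    "white_beaked_dolphin",
    "bottlenose_dolphin",
    "harbour_porpoise",
)

#: Canonical species groupings used for effect estimation.  Groups are
#: configuration, not code: analyses may pass their own mapping.
DEFAULT_SPECIES_GROUPS: dict[str, list[str]] = {
    "all birds": list(BIRD_SPECIES),
    "common and black guillemot": ["common_guillemot", "black_guillemot"],
    "common eider": ["common_eider"],
    "long-tailed duck": ["long_tailed_duck"],
    "all marine mammals": list(MAMMAL_SPECIES),
}

_SCALAR_FIELDS = (
    "trip_id",
    "boat_id",
    "date_set",
    "date_hauled",
    "mean_depth",
    "net_length",
    "n_nets",
    "net_height",
    "has_leb",
    "lumpfish_count",
)
_OPTIONAL_FIELDS = ("latitude", "longitude", "observer_onboard")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping between a delimited table and :class:`TrossaRecord`.

    ``columns`` maps record field names to table headers; ``bird_columns`` and
    ``mammal_columns`` map species labels to the headers holding their counts.
    The default dialect uses snake_case headers identical to the field and
    species names.  Unmapped table columns are preserved verbatim on write.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {f: f for f in _SCALAR_FIELDS + _OPTIONAL_FIELDS}
    )
    bird_columns: Mapping[str, str] = field(
        default_factory=lambda: {s: s for s in BIRD_SPECIES}
    )
    mammal_columns: Mapping[str, str] = field(
        default_factory=lambda: {s: s for s in MAMMAL_SPECIES}
    )


DEFAULT_DIALECT = TableDialect()


@dataclass(eq=False)
class TrossaRecord:
    """One net tier set and hauled once, with effort geometry and counts.

    Equality treats an absent species count and an explicit zero as the same
    thing, so a round-trip through a table that materialises zero columns
    still compares equal.
    """

    trip_id: str
    boat_id: str
    date_set: dt.date
    date_hauled: dt.date
    mean_depth: float
    net_length: float
    n_nets: int
    net_height: float
    has_leb: bool
    bird_counts: dict[str, int] = field(default_factory=dict)
    mammal_counts: dict[str, int] = field(default_factory=dict)
    lumpfish_count: int = 0
    latitude: float | None = None
    longitude: float | None = None
    observer_onboard: bool | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrossaRecord):
            return NotImplemented

        def nonzero(counts: Mapping[str, int]) -> dict[str, int]:
            return {k: v for k, v in counts.items() if v != 0}

        return (
            (
                self.trip_id, self.boat_id, self.date_set, self.date_hauled,
                self.mean_depth, self.net_length, self.n_nets, self.net_height,
                self.has_leb, self.lumpfish_count, self.latitude,
                self.longitude, self.observer_onboard, self.extras,
            )
            == (
                other.trip_id, other.boat_id, other.date_set, other.date_hauled,
                other.mean_depth, other.net_length, other.n_nets, other.net_height,
                other.has_leb, other.lumpfish_count, other.latitude,
                other.longitude, other.observer_onboard, other.extras,
            )
            and nonzero(self.bird_counts) == nonzero(other.bird_counts)
            and nonzero(self.mammal_counts) == nonzero(other.mammal_counts)
        )

    @property
    def soak_days(self) -> int:
        """Whole days between setting and hauling (the unit of exposure)."""
        return (self.date_hauled - self.date_set).days

    @property
    def total_birds(self) -> int:
        return sum(self.bird_counts.values())

    @property
    def total_mammals(self) -> int:
        return sum(self.mammal_counts.values())


@dataclass
class Violation:
    index: int
    rule: str
    message: str


@dataclass
class ValidationReport:
    """Result of :func:`validate_dataset`.

    ``violations`` are breaches of hard record invariants; ``flags`` mark
    legal-but-notable conditions (a soak longer than the 3-day regulatory
    maximum, allowed in bad weather).
    """

    n_records: int
    n_trips: int
    n_leb: int
    violations: list[Violation] = field(default_factory=list)
    flags: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class FleetDataset:
    """An ordered collection of trossa records grouped by fishing trip.

    The fishing trip is the resampling unit of the paired bootstrap: each
    deterrent trossa is compared against control trossas from its own trip.
    """

    records: list[TrossaRecord] = field(default_factory=list)
    species_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SPECIES_GROUPS.items()}
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_leb(self) -> int:
        return sum(r.has_leb for r in self.records)

    @property
    def trip_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.trip_id, None)
        return list(seen)

    @property
    def n_trips(self) -> int:
        return len(self.trip_ids)

    def trips(self) -> dict[str, list[TrossaRecord]]:
        out: dict[str, list[TrossaRecord]] = {}
        for r in self.records:
            out.setdefault(r.trip_id, []).append(r)
        return out

    def subset(self, predicate) -> "FleetDataset":
        return FleetDataset(
            records=[r for r in self.records if predicate(r)],
            species_groups={k: list(v) for k, v in self.species_groups.items()},
        )


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RowParseError(row, f"cannot parse boolean {value!r} in column {column!r}")


def _parse_date(value: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise RowParseError(row, f"bad date {value!r} in column {column!r}: {exc}") from None


def _parse_float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise RowParseError(row, f"bad number {value!r} in column {column!r}") from None


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(float(value)) if float(value) == int(float(value)) else int(value)
    except ValueError:
        raise RowParseError(row, f"bad integer {value!r} in column {column!r}") from None


def read_trossa_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT,
    species_groups: Mapping[str, Iterable[str]] | None = None,
) -> FleetDataset:
    """Read a delimited trossa table (CSV, UTF-8, header row) into a dataset.

    Required columns are the scalar fields of the dialect; species columns
    absent from the file are filled with zero counts, and file columns not
    mapped by the dialect are kept as record extras (and logged).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(df.columns)

    required = {f: dialect.columns[f] for f in _SCALAR_FIELDS}
    for fname, col in required.items():
        if col not in cols:
            raise SchemaError(f"missing required column {col!r} (field {fname!r})")
    optional = {
        f: dialect.columns.get(f)
        for f in _OPTIONAL_FIELDS
        if dialect.columns.get(f) in cols
    }

    bird_cols = {s: c for s, c in dialect.bird_columns.items() if c in cols}
    mammal_cols = {s: c for s, c in dialect.mammal_columns.items() if c in cols}
    mapped = (
        set(required.values())
        | set(optional.values())
        | set(bird_cols.values())
        | set(mammal_cols.values())
    )
    unmapped = [c for c in df.columns if c not in mapped]
    if unmapped:
        logger.warning(
            "%s: columns not in dialect are carried as extras: %s", path.name, unmapped
        )

    records: list[TrossaRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rec = TrossaRecord(
            trip_id=str(row[required["trip_id"]]),
            boat_id=str(row[required["boat_id"]]),
            date_set=_parse_date(row[required["date_set"]], i, required["date_set"]),
            date_hauled=_parse_date(row[required["date_hauled"]], i, required["date_hauled"]),
            mean_depth=_parse_float(row[required["mean_depth"]], i, required["mean_depth"]),
            net_length=_parse_float(row[required["net_length"]], i, required["net_length"]),
            n_nets=_parse_int(row[required["n_nets"]], i, required["n_nets"]),
            net_height=_parse_float(row[required["net_height"]], i, required["net_height"]),
            has_leb=_parse_bool(row[required["has_leb"]], i, required["has_leb"]),
            lumpfish_count=_parse_int(row[required["lumpfish_count"]], i, required["lumpfish_count"]),
            bird_counts={
                s: _parse_int(row[c] or "0", i, c) for s, c in bird_cols.items()
            },
            mammal_counts={
                s: _parse_int(row[c] or "0", i, c) for s, c in mammal_cols.items()
            },
            extras={c: row[c] for c in unmapped},
        )
        for s in dialect.bird_columns:
            rec.bird_counts.setdefault(s, 0)
        for s in dialect.mammal_columns:
            rec.mammal_counts.setdefault(s, 0)
        if "latitude" in optional and row[optional["latitude"]] != "":
            rec.latitude = _parse_float(row[optional["latitude"]], i, optional["latitude"])
        if "longitude" in optional and row[optional["longitude"]] != "":
            rec.longitude = _parse_float(row[optional["longitude"]], i, optional["longitude"])
        if "observer_onboard" in optional and row[optional["observer_onboard"]] != "":
            rec.observer_onboard = _parse_bool(
                row[optional["observer_onboard"]], i, optional["observer_onboard"]
            )
        records.append(rec)

    groups = (
        {k: list(v) for k, v in species_groups.items()}
        if species_groups is not None
        else None
    )
    return FleetDataset(records=records, **({"species_groups": groups} if groups else {}))


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_trossa_table(
    d: FleetDataset, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a dataset as CSV so that reading it back reproduces it exactly.

    Dates are ISO-8601, booleans ``true``/``false``, floats written with full
    precision (``repr``) so round-trips are bit-exact.
    """
    path = Path(path)
    headers = [dialect.columns[f] for f in _SCALAR_FIELDS]
    any_opt = {
        f: any(getattr(r, f) is not None for r in d.records) for f in _OPTIONAL_FIELDS
    }
    headers += [dialect.columns[f] for f in _OPTIONAL_FIELDS if any_opt[f]]
    bird_order = list(dialect.bird_columns)
    mammal_order = list(dialect.mammal_columns)
    headers += [dialect.bird_columns[s] for s in bird_order]
    headers += [dialect.mammal_columns[s] for s in mammal_order]
    extra_cols: list[str] = []
    for r in d.records:
        for c in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    headers += extra_cols

    rows = []
    for r in d.records:
        row = [_fmt(getattr(r, f)) for f in _SCALAR_FIELDS]
        row += [_fmt(getattr(r, f)) for f in _OPTIONAL_FIELDS if any_opt[f]]
        row += [_fmt(r.bird_counts.get(s, 0)) for s in bird_order]
        row += [_fmt(r.mammal_counts.get(s, 0)) for s in mammal_order]
        row += [_fmt(r.extras.get(c, "")) for c in extra_cols]
        rows.append(row)
    pd.DataFrame(rows, columns=headers).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


def validate_dataset(d: FleetDataset) -> ValidationReport:
    """Check every record invariant; violations are data, not exceptions."""
    report = ValidationReport(n_records=len(d), n_trips=d.n_trips, n_leb=d.n_leb)
    for i, r in enumerate(d.records):
        if r.date_hauled < r.date_set:
            report.violations.append(
                Violation(i, "date_order", "date_hauled precedes date_set")
            )
        elif r.soak_days < 1:
            report.violations.append(
                Violation(i, "soak_days", "soak shorter than one whole day")
            )
        elif r.soak_days > 3:
            report.flags.append(
                Violation(i, "soak_exceeds_3_days", f"soak of {r.soak_days} days")
            )
        if not r.mean_depth > 0:
            report.violations.append(
                Violation(i, "depth_positive", f"mean_depth {r.mean_depth} not > 0")
            )
        for name in ("net_length", "net_height"):
            v = getattr(r, name)
            if not v > 0:
                report.violations.append(
                    Violation(i, "geometry_positive", f"{name} {v} not > 0")
                )
        if r.n_nets < 1:
            report.violations.append(
                Violation(i, "geometry_positive", f"n_nets {r.n_nets} < 1")
            )
        counts: list[tuple[str, Any]] = [("lumpfish", r.lumpfish_count)]
        counts += list(r.bird_counts.items()) + list(r.mammal_counts.items())
        for label, c in counts:
            if isinstance(c, float) and c != int(c):
                report.violations.append(
                    Violation(i, "count_integer", f"{label} count {c} not integer")
                )
            elif c < 0:
                report.violations.append(
                    Violation(i, "count_negative", f"{label} count {c} negative")
                )
    return report


# ---------------------------------------------------------------------------
# configuration files


def load_species_groups(path: str | Path) -> dict[str, list[str]]:
    """Load species groupings from a YAML mapping of group name -> label list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: species-group file must be a mapping")
    return {str(k): [str(s) for s in v] for k, v in raw.items()}


def load_dialect(path: str | Path) -> TableDialect:
    """Load a table dialect from YAML with keys columns/bird_columns/mammal_columns."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = DEFAULT_DIALECT
    return TableDialect(
        columns={**dict(base.columns), **raw.get("columns", {})},
        bird_columns=raw.get("bird_columns", dict(base.bird_columns)),
        mammal_columns=raw.get("mammal_columns", dict(base.mammal_columns)),
    )
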