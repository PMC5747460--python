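"""Historical occurrence records: reading, first-record extraction, diachronic filtering.

A record is one dated, georeferenced report of the species in a territorial
unit (TU; NUTS-3 in Europe, GADM elsewhere), flagged as ``cultivated`` or
``wild``.  The year is a *terminus ante quem*: the species was present no
later than that year.  The central transformation is the derivation of a
"synthetic table" keeping, for every (TU, status) pair, only the earliest
record — later reports of an already-reported unit carry no information
about arrival order and would overweight well-surveyed localities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "RecordSet",
    "RecordValidationError",
    "SchemaError",
    "read_records",
    "write_records",
    "first_records",
    "filter_until",
    "summarize",
    "to_geojson",
]

#: Bit-exact CSV header for occurrence files.
CSV_COLUMNS = ["record_id", "tu_id", "tu_name", "lon", "lat", "year", "status", "source"]

STATUSES = ("cultivated", "wild")
YEAR_MIN, YEAR_MAX = 1500, 2100


class SchemaError(ValueError):
    """The input file is missing a required column."""


class RecordValidationError(ValueError):
    """One or more rows failed validation; ``.errors`` lists (line, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated, georeferenced first report in a territorial unit."""

    record_id: str
    tu_id: str
    tu_name: str
    lon: float
    lat: float
    year: int
    status: str
    source: str = ""

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if not -180.0 <= self.lon <= 180.0:
            problems.append(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            problems.append(f"lat {self.lat} outside [-90, 90]")
        if not YEAR_MIN <= self.year <= YEAR_MAX:
            problems.append(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")
        if self.status not in STATUSES:
            problems.append(f"status {self.status!r} not in {STATUSES}")
        return problems


@dataclass
class RecordSet:
    """Ordered collection of occurrence records with unique ids."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise ValueError(f"duplicate record_id(s): {sorted(dup)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.DataFrame([asdict(r) for r in self.records], columns=CSV_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "RecordSet":
        recs = [
            OccurrenceRecord(
                record_id=str(row.record_id),
                tu_id=str(row.tu_id),
                tu_name=str(row.tu_name),
                lon=float(row.lon),
                lat=float(row.lat),
                year=int(row.year),
                status=str(row.status),
                source=str(getattr(row, "source", "") or ""),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs, provenance)

    def coordinates(self):
        """(n, 2) array of (lon, lat)."""
        import numpy as np

        return np.array([[r.lon, r.lat] for r in self.records], dtype=float).reshape(-1, 2)


def _parse_float(text: str) -> float:
    # historical tables use comma decimals; accept both on read
    return float(str(text).strip().replace(",", "."))


def read_records(path: str | Path, sep: str | None = None, lenient: bool = False) -> RecordSet:
    """Read an occurrence CSV into a :class:`RecordSet`.

    Parameters
    ----------
    path : str or Path
        CSV with header ``record_id,tu_id,tu_name,lon,lat,year,status,source``.
        Separator ``,`` or ``;`` (auto-detected when `sep` is None); decimal
        separators ``.`` and ``,`` both accepted.
    lenient : bool
        If True, rows failing validation are dropped (and reported on the
        returned set's ``provenance``); otherwise any hard error raises
        :class:`RecordValidationError` listing the offending lines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        header = path.open(encoding="utf-8").readline()
        sep = ";" if header.count(";") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if "source" not in df.columns:
        df["source"] = ""

    records: list[OccurrenceRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            rec = OccurrenceRecord(
                record_id=str(row.record_id).strip(),
                tu_id=str(row.tu_id).strip(),
                tu_name=str(row.tu_name).strip(),
                lon=_parse_float(row.lon),
                lat=_parse_float(row.lat),
                year=int(str(row.year).strip()),
                status=str(row.status).strip().lower(),
                source=str(row.source),
            )
        except (ValueError, TypeError) as exc:
            errors.append((line_no, f"unparsable field: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            errors.append((line_no, "; ".join(problems)))
            continue
        records.append(rec)

    if errors and not lenient:
        raise RecordValidationError(errors)
    prov = f"read from {path.name}"
    if errors:
        prov += f" ({len(errors)} row(s) dropped)"
    return RecordSet(records, provenance=prov)


def write_records(rs: RecordSet, path: str | Path, sep: str = ",") -> None:
    """Write a RecordSet as CSV (UTF-8, '.' decimals)."""
    rs.to_dataframe().to_csv(path, sep=sep, index=False, encoding="utf-8")


def first_records(rs: RecordSet) -> RecordSet:
    """Keep, for each (tu_id, status) pair, only the earliest record.

    Cultivated and wild streams are independent: a territorial unit may
    contribute one cultivated and one wild first record.  Year ties are
    broken by lexicographically smallest ``record_id``.  Input order of the
    surviving records is preserved.
    """
    best: dict[tuple[str, str], OccurrenceRecord] = {}
    for rec in rs:
        key = (rec.tu_id, rec.status)
        cur = best.get(key)
        if cur is None or (rec.year, rec.record_id) < (cur.year, cur.record_id):
            best[key] = rec
    keep = {id(r) for r in best.values()}
    return RecordSet([r for r in rs if id(r) in keep], provenance=rs.provenance + " | first records per (TU, status)")


def filter_until(rs: RecordSet, cutoff: int) -> RecordSet:
    """Retain records with year <= cutoff (order preserved)."""
    return RecordSet([r for r in rs if r.year <= int(cutoff)], provenance=rs.provenance + f" | until {cutoff}")


def summarize(rs: RecordSet) -> dict:
    """Exact counts by status and TU plus the year range."""
    n_cult = sum(1 for r in rs if r.status == "cultivated")
    by_tu: dict[str, int] = {}
    for r in rs:
        by_tu[r.tu_id] = by_tu.get(r.tu_id, 0) + 1
    years = [r.year for r in rs]
    return {
        "total": len(rs),
        "cultivated": n_cult,
        "wild": len(rs) - n_cult,
        "n_territorial_units": len(by_tu),
        "by_tu": by_tu,
        "year_min": min(years) if years else None,
        "year_max": max(years) if years else None,
    }


def to_geojson(rs: RecordSet, path: str | Path | None = None, extra: dict | None = None) -> dict:
    """Export as a GeoJSON FeatureCollection of Points (properties = all fields).

    `extra` maps record_id -> dict of additional properties (e.g. cluster labels).
    """
    features = []
    for r in rs:
        props = asdict(r)
        props.pop("lon")
        props.pop("lat")
        if extra and r.record_id in extra:
            props.update(extra[r.record_id])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc), encoding="utf-8")
    return fc
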