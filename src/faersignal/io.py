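"""Readers and writers for the FAERS quarterly ASCII dialect.

Tables are plain text, one record per line, ``$``-delimited, with an
upper-case header line.  Dates appear as 8-digit ``YYYYMMDD`` strings but
may be truncated to ``YYYYMM`` or ``YYYY`` (partial dates) or empty.
All readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import gzip
import logging
from functools import lru_cache
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import SchemaError

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")

#: canonical column order used when writing each table kind
TABLE_COLUMNS = {
    "DEMO": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
        "SEX", "OCCP_COD", "REPORTER_COUNTRY",
    ],
    "DRUG": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "PT"],
    "THER": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
}

#: columns that must be present for a file to be readable at all
REQUIRED_COLUMNS = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT"],
    "DRUG": ["PRIMARYID", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "PT"],
    "THER": ["PRIMARYID", "START_DT"],
}


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_date(self) -> _dt.date:
        """Full :class:`datetime.date`; only valid at day precision."""
        if self.precision != "day":
            raise ValueError(f"partial date {self} has no day precision")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_date(text: Optional[str]) -> Optional[PartialDate]:
    """Parse a FAERS date string; total function, never raises.

    8 digits -> day precision, 6 -> month, 4 -> year.  Anything else,
    including invalid calendar combinations, parses to ``None``.
    """
    if text is None:
        return None
    return _parse_date_cached(text.strip())


@lru_cache(maxsize=1 << 16)
def _parse_date_cached(text: str) -> Optional[PartialDate]:
    if not text.isdigit():
        return None
    try:
        if len(text) == 8:
            y, m, d = int(text[:4]), int(text[4:6]), int(text[6:8])
            if not (1 <= m <= 12) or y < 1:
                return None
            if not (1 <= d <= calendar.monthrange(y, m)[1]):
                return None
            return PartialDate(y, m, d)
        if len(text) == 6:
            y, m = int(text[:4]), int(text[4:6])
            if not (1 <= m <= 12) or y < 1:
                return None
            return PartialDate(y, m)
        if len(text) == 4:
            y = int(text)
            if y < 1:
                return None
            return PartialDate(y)
    except ValueError:  # pragma: no cover - isdigit() guards above
        return None
    return None


def format_date(value: Union[PartialDate, _dt.date, None]) -> str:
    if value is None:
        return ""
    if isinstance(value, _dt.date):
        return f"{value.year:04d}{value.month:02d}{value.day:02d}"
    return str(value)


@dataclass(frozen=True)
class ReportRecord:
    """One (possibly not-yet-deduplicated) safety report from DEMO."""

    primaryid: int
    caseid: int
    fda_dt: _dt.date
    event_dt: Optional[PartialDate] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    occp_cod: Optional[str] = None
    reporter_country: Optional[str] = None


@dataclass(frozen=True)
class DrugRow:
    primaryid: int
    drug_seq: int
    role_cod: str
    drugname: str


@dataclass(frozen=True)
class ReactionRow:
    primaryid: int
    pt: str


@dataclass(frozen=True)
class TherapyRow:
    primaryid: int
    dsg_drug_seq: int
    start_dt: Optional[PartialDate] = None


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _parse_demo(fields: dict) -> ReportRecord:
    fda = parse_date(fields.get("FDA_DT"))
    if fda is None or fda.precision != "day":
        raise ValueError("FDA_DT must be a complete date")
    age_text = fields.get("AGE", "")
    age = float(age_text) if age_text not in ("", None) else None
    if age is not None and age < 0:
        raise ValueError("negative AGE")
    return ReportRecord(
        primaryid=int(fields["PRIMARYID"]),
        caseid=int(fields["CASEID"]),
        fda_dt=fda.to_date(),
        event_dt=parse_date(fields.get("EVENT_DT")),
        age=age,
        age_cod=fields.get("AGE_COD") or None,
        sex=fields.get("SEX") or None,
        occp_cod=fields.get("OCCP_COD") or None,
        reporter_country=fields.get("REPORTER_COUNTRY") or None,
    )


def _parse_drug(fields: dict) -> DrugRow:
    return DrugRow(
        primaryid=int(fields["PRIMARYID"]),
        drug_seq=int(fields.get("DRUG_SEQ") or 1),
        role_cod=fields["ROLE_COD"].strip().upper(),
        drugname=fields["DRUGNAME"],
    )


def _parse_reac(fields: dict) -> ReactionRow:
    pt = fields["PT"]
    if not pt:
        raise ValueError("empty PT")
    return ReactionRow(primaryid=int(fields["PRIMARYID"]), pt=pt)


def _parse_ther(fields: dict) -> TherapyRow:
    return TherapyRow(
        primaryid=int(fields["PRIMARYID"]),
        dsg_drug_seq=int(fields.get("DSG_DRUG_SEQ") or 1),
        start_dt=parse_date(fields.get("START_DT")),
    )


_PARSERS = {
    "DEMO": _parse_demo,
    "DRUG": _parse_drug,
    "REAC": _parse_reac,
    "THER": _parse_ther,
}


def read_table(path: Union[str, Path], table_kind: str, delimiter: str = "$") -> list:
    """Read one FAERS-dialect table into typed rows.

    Unknown columns are ignored; rows that fail to parse are counted,
    logged, and skipped.  A missing required column raises
    :class:`~faersignal.errors.SchemaError`.
    """
    table_kind = table_kind.upper()
    if table_kind not in _PARSERS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    parser = _PARSERS[table_kind]

    rows = []
    malformed = 0
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(REQUIRED_COLUMNS[table_kind][0], str(path))
        header = [h.strip().upper() for h in header_line.rstrip("\n").split(delimiter)]
        for col in REQUIRED_COLUMNS[table_kind]:
            if col not in header:
                raise SchemaError(col, str(path))
        index = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split(delimiter)
            fields = {
                name: (parts[i].strip() if i < len(parts) else "")
                for name, i in index.items()
            }
            try:
                rows.append(parser(fields))
            except (ValueError, KeyError):
                malformed += 1
    logger.info(
        "%s: read %d rows from %s (%d malformed skipped)",
        table_kind, len(rows), path, malformed,
    )
    return rows


def write_table(path: Union[str, Path], table_kind: str,
                rows: Iterable[Sequence], delimiter: str = "$") -> None:
    """Write pre-formatted string tuples under the canonical header."""
    table_kind = table_kind.upper()
    columns = TABLE_COLUMNS[table_kind]
    with _open_text(path, "wt") as fh:
        fh.write(delimiter.join(columns) + "\n")
        for row in rows:
            fh.write(delimiter.join(str(v) for v in row) + "\n")


def _format_demo(r: ReportRecord) -> tuple:
    age = "" if r.age is None else (f"{r.age:g}")
    return (
        r.primaryid, r.caseid, format_date(r.fda_dt), format_date(r.event_dt),
        age, r.age_cod or "", r.sex or "", r.occp_cod or "",
        r.reporter_country or "",
    )


def write_dataset(out_dir: Union[str, Path], demo: Sequence[ReportRecord],
                  drug: Sequence[DrugRow], reac: Sequence[ReactionRow],
                  ther: Sequence[TherapyRow], delimiter: str = "$") -> dict:
    """Write the four-table file set; returns {kind: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    writers = {
        "DEMO": (demo, _format_demo),
        "DRUG": (drug, lambda r: (r.primaryid, r.drug_seq, r.role_cod, r.drugname)),
        "REAC": (reac, lambda r: (r.primaryid, r.pt)),
        "THER": (ther, lambda r: (r.primaryid, r.dsg_drug_seq,
                                  format_date(r.start_dt))),
    }
    for kind, (rows, fmt) in writers.items():
        path = out_dir / f"{kind}.txt"
        write_table(path, kind, (fmt(r) for r in rows), delimiter)
        paths[kind] = path
    return paths


def read_dataset(data_dir: Union[str, Path], delimiter: str = "$") -> dict:
    """Read DEMO/DRUG/REAC/THER from a directory into typed row lists."""
    data_dir = Path(data_dir)
    out = {}
    for kind in TABLE_COLUMNS:
        path = data_dir / f"{kind}.txt"
        if not path.exists() and (data_dir / f"{kind}.txt.gz").exists():
            path = data_dir / f"{kind}.txt.gz"
        out[kind] = read_table(path, kind, delimiter)
    return out
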