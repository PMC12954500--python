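"""Reading, validating and writing time-loss injury surveillance records.

The tabular layout follows the football consensus-statement style of injury
surveillance: one row per time-loss injury carrying the player identifier,
the injury date and season, the coded body part and side, the tissue nature
(muscle, tendon, ligament, ...), an optional specific diagnosis category
("Hamstring Muscle Injury", "ACL", ...), onset, severity in days lost, a
contact flag, the activity context and the recurrence class assigned by the
team clinician.

The canonical in-memory container is a :class:`RecordSet`, a thin wrapper
around a :class:`pandas.DataFrame` with a fixed column schema plus provenance
(source, dialect, accepted/rejected row counts).  Row-level validation on
ingest goes through the pydantic :class:`InjuryRecord` model; rows that fail
to parse are rejected with a reason, never silently dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

__all__ = [
    "Side",
    "Onset",
    "Contact",
    "Context",
    "RecurrenceClass",
    "InjuryRecord",
    "Provenance",
    "RecordSet",
    "ValidationReport",
    "COLUMNS",
    "SIDE_TOKENS",
    "read_records",
    "validate_records",
    "write_records",
    "derive_season_labels",
]


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    BILATERAL = "bilateral"
    UNSPECIFIED = "unspecified"


#: single-letter tokens used when the side is folded into the body-part label
SIDE_TOKENS: Mapping[str, str] = {
    "left": "L",
    "right": "R",
    "bilateral": "B",
    "unspecified": "U",
}


class Onset(str, Enum):
    SUDDEN = "sudden"
    GRADUAL = "gradual"


class Contact(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Context(str, Enum):
    TRAINING = "training"
    MATCH = "match"
    NOT_APPLICABLE = "not_applicable"


class RecurrenceClass(str, Enum):
    INDEX = "index"
    REINJURY = "reinjury"
    EXACERBATION = "exacerbation"
    UNKNOWN = "unknown"


#: canonical column order of the delimited layout
COLUMNS: Sequence[str] = (
    "player_id",
    "injury_date",
    "season_label",
    "body_part",
    "side",
    "nature",
    "category",
    "onset",
    "severity_days",
    "contact",
    "context",
    "recurrence_class",
)

_ENUM_FIELDS = {
    "side": Side,
    "onset": Onset,
    "contact": Contact,
    "context": Context,
    "recurrence_class": RecurrenceClass,
}


class InjuryRecord(BaseModel):
    """One coded time-loss injury.

    ``player_id`` and ``body_part`` may be empty on ingest (surveillance
    exports do contain such rows); the preprocessing stage removes them.
    ``severity_days`` is days of time loss and must be non-negative.
    """

    player_id: str = ""
    injury_date: dt.date
    season_label: str = ""
    body_part: str = ""
    side: Side = Side.UNSPECIFIED
    nature: str = ""
    category: str = ""
    onset: Onset | None = None
    severity_days: int = Field(default=0, ge=0)
    contact: Contact = Contact.UNKNOWN
    context: Context = Context.NOT_APPLICABLE
    recurrence_class: RecurrenceClass = RecurrenceClass.UNKNOWN

    @field_validator("player_id", "body_part", "nature", "category", "season_label", mode="before")
    @classmethod
    def _strip(cls, v: object) -> object:
        return v.strip() if isinstance(v, str) else v


@dataclass
class Provenance:
    """Where a :class:`RecordSet` came from and how ingest went."""

    source: str = "<memory>"
    dialect: str = "memory"
    rows_read: int = 0
    rows_accepted: int = 0
    rows_rejected: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def check(self) -> None:
        if self.rows_accepted + self.rows_rejected != self.rows_read:
            raise ValueError("provenance counts inconsistent: accepted + rejected != read")


@dataclass
class RecordSet:
    """Ordered collection of injury records backed by a DataFrame.

    The frame index preserves original input row order across filtering
    stages; downstream same-day tie-breaking relies on it.
    """

    frame: pd.DataFrame
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.records)

    @property
    def records(self) -> list[InjuryRecord]:
        out = []
        for _, row in self.frame.iterrows():
            d = row.to_dict()
            date = d["injury_date"]
            if isinstance(date, pd.Timestamp):
                d["injury_date"] = date.date()
            if d.get("onset") in ("", None):
                d["onset"] = None
            out.append(InjuryRecord(**d))
        return out

    @classmethod
    def from_records(cls, records: Iterable[InjuryRecord], provenance: Provenance | None = None) -> "RecordSet":
        rows = [r.model_dump() for r in records]
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(_coerce_frame(frame), provenance or Provenance(rows_read=len(rows), rows_accepted=len(rows)))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: Provenance | None = None) -> "RecordSet":
        return cls(_coerce_frame(frame.copy()), provenance or Provenance(
            rows_read=len(frame), rows_accepted=len(frame)))

    def with_frame(self, frame: pd.DataFrame) -> "RecordSet":
        """New RecordSet sharing this one's provenance (used by filters)."""
        return RecordSet(frame, self.provenance)


def _coerce_frame(frame: pd.DataFrame) -> pd.DataFrame:
    for col in COLUMNS:
        if col not in frame.columns:
            frame[col] = 0 if col == "severity_days" else ""
    frame["injury_date"] = pd.to_datetime(frame["injury_date"])
    for name, enum in _ENUM_FIELDS.items():
        frame[name] = frame[name].map(lambda v: v.value if isinstance(v, Enum) else ("" if v is None else str(v)))
    for name in ("player_id", "season_label", "body_part", "nature", "category"):
        frame[name] = frame[name].astype(str).str.strip()
    return frame


def derive_season_labels(dates: pd.Series, season_start_month: int = 7) -> pd.Series:
    """Season label ("2015-16") of each date for a season starting in the given month.

    Professional seasons span calendar years (default start July); a date
    before the start month belongs to the season that began the previous year.
    """
    dates = pd.to_datetime(dates)
    start_year = dates.dt.year.where(dates.dt.month >= season_start_month, dates.dt.year - 1)
    return start_year.astype(str) + "-" + ((start_year + 1) % 100).map("{:02d}".format)


# ---------------------------------------------------------------------------
# ingest

DEFAULT_SCHEMA: Mapping[str, str] = {c: c for c in COLUMNS}
_MANDATORY = ("player_id", "injury_date", "body_part")


def _parse_date(text: str, date_formats: Sequence[str]) -> dt.date:
    text = text.strip()
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        for fmt in date_formats:
            try:
                return dt.datetime.strptime(text, fmt).date()
            except ValueError:
                continue
    raise ValueError(f"bad date: {text!r}")


def _parse_row(raw: Mapping[str, str], date_formats: Sequence[str]) -> InjuryRecord:
    data: dict = {}
    for name in COLUMNS:
        if name not in raw:
            continue
        text = str(raw[name]).strip()
        if name == "injury_date":
            data[name] = _parse_date(text, date_formats)
        elif name == "severity_days":
            if text != "":
                try:
                    data[name] = int(float(text))
                except ValueError:
                    raise ValueError(f"bad severity: {text!r}")
        elif name in _ENUM_FIELDS:
            if text != "":
                try:
                    data[name] = _ENUM_FIELDS[name](text.lower())
                except ValueError:
                    raise ValueError(f"bad {name}: {text!r}")
        else:
            data[name] = text
    try:
        return InjuryRecord(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        raise ValueError(f"bad {'.'.join(str(p) for p in first['loc'])}: {first['msg']}")


def read_records(
    path: str | Path,
    dialect: str = "delimited",
    schema_config: Mapping[str, str] | None = None,
    sep: str = ",",
    sheet: int | str = 0,
    date_formats: Sequence[str] = (),
) -> RecordSet:
    """Read surveillance records from a delimited file or spreadsheet.

    Parameters
    ----------
    path : file to read; missing file is fatal.
    dialect : "delimited" (comma/tab text) or "spreadsheet" (Excel workbook).
    schema_config : mapping from canonical field name to the column name used
        in the file; defaults to the canonical names themselves.
    sep : delimiter for the delimited dialect.
    sheet : sheet index or name for the spreadsheet dialect.
    date_formats : extra ``strptime`` formats tried after ISO.

    Rows whose date, enum or severity fields fail to parse are rejected (not
    fatal) and logged with a reason in the returned provenance; a missing
    mandatory mapped column (player_id, injury_date, body_part) is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "delimited":
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    elif dialect == "spreadsheet":
        raw = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    mapping = dict(DEFAULT_SCHEMA)
    mapping.update(schema_config or {})
    for canonical in _MANDATORY:
        if mapping[canonical] not in raw.columns:
            raise ValueError(f"mandatory column {mapping[canonical]!r} (for {canonical}) missing from header")
    present = {canon: col for canon, col in mapping.items() if col in raw.columns}

    accepted: list[dict] = []
    rejected: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(raw.iterrows()):
        payload = {canon: row[col] for canon, col in present.items()}
        try:
            rec = _parse_row(payload, date_formats)
        except ValueError as exc:
            rejected.append((i, str(exc)))
            continue
        accepted.append(rec.model_dump())

    frame = pd.DataFrame(accepted, columns=list(COLUMNS))
    prov = Provenance(
        source=str(path),
        dialect=dialect,
        rows_read=len(raw),
        rows_accepted=len(accepted),
        rows_rejected=len(rejected),
        rejected=rejected,
    )
    prov.check()
    return RecordSet(_coerce_frame(frame), prov)


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    """Per-rule invariant violations; purely informational, never mutates."""

    violations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rule, _ in self.violations:
            out[rule] = out.get(rule, 0) + 1
        return out

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.violations


def validate_records(
    rs: RecordSet,
    window: tuple[dt.date | str, dt.date | str] | None = None,
) -> ValidationReport:
    """Report every invariant violation in a RecordSet without modifying it.

    Checked rules: negative severity, empty player_id, empty body_part,
    missing date, date outside the study window, malformed enum token.
    """
    f = rs.frame
    report = ValidationReport()
    for idx in f.index[f["severity_days"] < 0]:
        report.violations.append(("negative_severity", int(idx)))
    for idx in f.index[f["player_id"] == ""]:
        report.violations.append(("empty_player_id", int(idx)))
    for idx in f.index[f["body_part"] == ""]:
        report.violations.append(("empty_body_part", int(idx)))
    dates = pd.to_datetime(f["injury_date"], errors="coerce")
    for idx in f.index[dates.isna()]:
        report.violations.append(("missing_date", int(idx)))
    if window is not None:
        lo, hi = (pd.Timestamp(w) for w in window)
        bad = dates.notna() & ((dates < lo) | (dates > hi))
        for idx in f.index[bad]:
            report.violations.append(("out_of_window", int(idx)))
    for name, enum in _ENUM_FIELDS.items():
        ok = {e.value for e in enum} | {""}
        for idx in f.index[~f[name].isin(ok)]:
            report.violations.append((f"bad_{name}", int(idx)))
    return report


def write_records(rs: RecordSet, path: str | Path, dialect: str = "delimited", sep: str = ",") -> Path:
    """Write a RecordSet in the canonical column order.

    Round-trip contract: ``read_records(write_records(rs))`` reproduces every
    field value.  Enum fields are serialized as their canonical lowercase
    tokens, dates as ISO.
    """
    path = Path(path)
    out = rs.frame.reindex(columns=list(COLUMNS)).copy()
    out["injury_date"] = pd.to_datetime(out["injury_date"]).dt.strftime("%Y-%m-%d")
    if dialect == "delimited":
        out.to_csv(path, sep=sep, index=False)
    elif dialect == "spreadsheet":
        out.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path
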