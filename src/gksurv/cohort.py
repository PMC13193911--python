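"""Lesion-level cohort schema and delimited-text I/O.

One row of a cohort table describes one treated radiosurgical target: the
patient it belongs to, baseline clinical covariates, tumor and molecular
covariates, the radiosurgical plan, and right-censored time to local failure.
A patient may contribute more than one target; downstream validation code
treats the patient as the resampling unit, so ``patient_id`` is load-bearing.

Missing values are first-class: every covariate except the identifiers, the
follow-up time and the event flag may be absent, and the reader coerces
unparseable or out-of-range entries to missing with a warning rather than
failing the whole file.  Follow-up time and the event flag are mandatory —
rows lacking them are a hard error, mirroring the exclusion of targets
without valid time-to-event information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LesionRecord",
    "CohortTable",
    "CohortSchemaError",
    "RowRejectionError",
    "read_cohort",
    "write_cohort",
    "load_schema_descriptor",
    "KPS_LEVELS",
    "SEX_LEVELS",
    "MGMT_LEVELS",
    "EGFR_LEVELS",
    "PTEN_LEVELS",
    "TERT_LEVELS",
    "CHR7P10Q_LEVELS",
    "ANATOMIC_LEVELS",
    "TUMOR_LOC_LEVELS",
]

# Declared categorical levels.  Anything outside these becomes missing on read.
SEX_LEVELS = ("M", "F")
MGMT_LEVELS = ("methyl", "unmethyl")
EGFR_LEVELS = ("ampl", "unampl", "mut", "unmut")
PTEN_LEVELS = ("mut", "umut")
TERT_LEVELS = ("mut", "unmut")
CHR7P10Q_LEVELS = ("yes", "no")
ANATOMIC_LEVELS = (1, 2, 3, 4, 5, 6)  # frontal, parietal, occipital, temporal, cerebellar, other/deep
TUMOR_LOC_LEVELS = (1, 2, 3)  # cortical, deep/midline, multifocal
KPS_LEVELS = tuple(range(40, 101, 10))


class CohortSchemaError(ValueError):
    """A mandatory column is absent or the header cannot be interpreted."""


class RowRejectionError(ValueError):
    """One or more rows carry missing or non-positive time-to-event data."""

    def __init__(self, message: str, row_indices: list[int]):
        super().__init__(message)
        self.row_indices = row_indices


@dataclass
class LesionRecord:
    """One treated radiosurgical target with plan, covariates and outcome."""

    patient_id: str
    lesion_id: str
    time_months: float
    event: int
    age_years: Optional[float] = None
    sex: Optional[str] = None
    kps: Optional[int] = None
    volume_cm3: Optional[float] = None
    anatomic_loc: Optional[int] = None
    tumor_loc: Optional[int] = None
    dose_gy: Optional[float] = None
    isodose_pct: Optional[float] = None
    max_gy: Optional[float] = None
    coverage: Optional[float] = None
    mgmt: Optional[str] = None
    egfr: Optional[str] = None
    pten: Optional[str] = None
    tert: Optional[str] = None
    chr7p10q: Optional[str] = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months is None or not self.time_months > 0:
            raise ValueError(
                f"time_months must be positive, got {self.time_months!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")

    def replace(self, **changes: Any) -> "LesionRecord":
        return dataclasses.replace(self, **changes)


# column name -> (python type, validator); validators return a cleaned value
# or None for out-of-range input.
def _pos_real(x: float) -> Optional[float]:
    return x if x > 0 else None


def _nonneg_real(x: float) -> Optional[float]:
    return x if x >= 0 else None


def _unit_interval(x: float) -> Optional[float]:
    return x if 0.0 <= x <= 1.0 else None


def _isodose(x: float) -> Optional[float]:
    return x if 0.0 < x <= 100.0 else None


def _kps(x: float) -> Optional[int]:
    xi = int(x)
    return xi if (xi == x and xi in KPS_LEVELS) else None


def _level_validator(levels: tuple) -> Any:
    def check(x: Any) -> Optional[Any]:
        return x if x in levels else None

    return check


_NUMERIC_FIELDS: dict[str, Any] = {
    "age_years": _nonneg_real,
    "volume_cm3": _pos_real,
    "dose_gy": _pos_real,
    "isodose_pct": _isodose,
    "max_gy": _pos_real,
    "coverage": _unit_interval,
    "kps": _kps,
}

_CATEGORICAL_FIELDS: dict[str, tuple] = {
    "sex": SEX_LEVELS,
    "anatomic_loc": ANATOMIC_LEVELS,
    "tumor_loc": TUMOR_LOC_LEVELS,
    "mgmt": MGMT_LEVELS,
    "egfr": EGFR_LEVELS,
    "pten": PTEN_LEVELS,
    "tert": TERT_LEVELS,
    "chr7p10q": CHR7P10Q_LEVELS,
}

_INT_CATEGORICALS = {"anatomic_loc", "tumor_loc"}

SCHEMA_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "lesion_id",
    "age_years",
    "sex",
    "kps",
    "volume_cm3",
    "anatomic_loc",
    "tumor_loc",
    "dose_gy",
    "isodose_pct",
    "max_gy",
    "coverage",
    "mgmt",
    "egfr",
    "pten",
    "tert",
    "chr7p10q",
    "time_months",
    "event",
)

# Verbose clinical-export headers mapped onto machine-usable schema names.
# Matching is case-insensitive on the stripped header text.
HEADER_ALIASES: dict[str, str] = {
    "age at diagnosis": "age_years",
    "age": "age_years",
    "sex (m/f)": "sex",
    "kps before srs or re-rt for recurrence": "kps",
    "kps before gkrs": "kps",
    "pre-srs/rt contrast-enhancing tumor volume in cm3 (incl. necrosis)": "volume_cm3",
    "pre-gkrs contrast-enhancing tumor volume, cm3": "volume_cm3",
    "anatomic localization (1: frontal, 2: parietal, 3: occipital, 4: temporal,"
    " 5: cerebellar, 6: others including deep midline structures)": "anatomic_loc",
    "anatomic localization": "anatomic_loc",
    "tumor localization (1: cortical (sub-cortical)/2: deep-seated (basal"
    " ganglia/thalamus) or midline/3: multifocal)": "tumor_loc",
    "tumor localization": "tumor_loc",
    "srs dose (gy)": "dose_gy",
    "prescription dose, gy": "dose_gy",
    "isodose line (%)": "isodose_pct",
    "prescription isodose line, %": "isodose_pct",
    "max (gy)": "max_gy",
    "coverage": "coverage",
    "mgmt (methyl/unmethyl/n.a.)": "mgmt",
    "mgmt status": "mgmt",
    "egfr amplification (ampl/non-ampl)": "egfr",
    "pten (mut/umut)": "pten",
    "pten status": "pten",
    "tert (mut/unmut)": "tert",
    "tert status": "tert",
    "chromosome 7+/10- (yes/no)": "chr7p10q",
    "time to local failure or last follow-up (months)": "time_months",
    "local failure (1/0)": "event",
}

MANDATORY_FIELDS = ("time_months", "event")


@dataclass
class CohortTable:
    """Ordered collection of lesion records with a provenance tag.

    ``(patient_id, lesion_id)`` pairs are unique; model-fitting entry points
    additionally require at least one observed local failure.
    """

    records: list[LesionRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [(r.patient_id, r.lesion_id) for r in self.records]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate (patient_id, lesion_id) pair: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LesionRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> LesionRecord:
        return self.records[i]

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, indices: Iterable[int], provenance: str = "") -> "CohortTable":
        return CohortTable(
            [self.records[i] for i in indices],
            provenance or self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Schema columns as an object-dtype frame; missing values are None."""
        rows = []
        for r in self.records:
            d = {c: getattr(r, c) for c in SCHEMA_COLUMNS}
            d.update(r.extra)
            rows.append(d)
        return pd.DataFrame(rows, dtype=object)


def _canonical(name: str) -> str:
    key = name.strip().lower()
    if key in HEADER_ALIASES:
        return HEADER_ALIASES[key]
    return key


def _parse_cell(col: str, raw: str, row_idx: int) -> Any:
    """Parse one cell; out-of-range/unparseable covariates become None."""
    raw = raw.strip()
    if raw == "":
        return None
    if col in _NUMERIC_FIELDS:
        try:
            val = float(raw)
        except ValueError:
            logger.warning("row %d: unparseable %s=%r treated as missing", row_idx, col, raw)
            return None
        if math.isnan(val):
            return None
        cleaned = _NUMERIC_FIELDS[col](val)
        if cleaned is None:
            logger.warning("row %d: out-of-range %s=%r treated as missing", row_idx, col, raw)
        return cleaned
    if col in _CATEGORICAL_FIELDS:
        if col in _INT_CATEGORICALS:
            try:
                value: Any = int(float(raw))
            except ValueError:
                logger.warning("row %d: unparseable %s=%r treated as missing", row_idx, col, raw)
                return None
        else:
            value = raw
        cleaned = _level_validator(_CATEGORICAL_FIELDS[col])(value)
        if cleaned is None:
            logger.warning("row %d: off-schema %s=%r treated as missing", row_idx, col, raw)
        return cleaned
    return raw


def read_cohort(path: str | Path, delimiter: str = ",") -> CohortTable:
    """Read a delimited cohort file into a :class:`CohortTable`.

    The header must name every schema field (verbose clinical headers are
    canonicalized through the alias map); extra columns are preserved as
    opaque string annotations.  Covariate cells that cannot be parsed or fall
    outside the declared range become missing with a logged warning.  Rows
    with missing or non-positive ``time_months`` or an invalid ``event`` flag
    raise :class:`RowRejectionError` naming the offending row indices.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    colmap = {c: _canonical(c) for c in df.columns}
    df = df.rename(columns=colmap)
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError(
            f"cohort file {path} lacks mandatory column(s): {', '.join(missing_cols)}"
        )
    extra_cols = [c for c in df.columns if c not in SCHEMA_COLUMNS]

    bad_rows: list[int] = []
    records: list[LesionRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            t = float(row_d["time_months"])
            ev = float(row_d["event"])
        except (ValueError, TypeError):
            bad_rows.append(i)
            continue
        if not t > 0 or math.isnan(t) or ev not in (0.0, 1.0):
            bad_rows.append(i)
            continue
        kwargs: dict[str, Any] = {
            "patient_id": str(row_d["patient_id"]).strip(),
            "lesion_id": str(row_d["lesion_id"]).strip(),
            "time_months": t,
            "event": int(ev),
        }
        for col in SCHEMA_COLUMNS:
            if col in ("patient_id", "lesion_id", "time_months", "event"):
                continue
            kwargs[col] = _parse_cell(col, str(row_d[col]), i)
        kwargs["extra"] = {c: str(row_d[c]) for c in extra_cols}
        records.append(LesionRecord(**kwargs))

    if bad_rows:
        raise RowRejectionError(
            "time-to-event or event flag missing or non-positive in row(s): "
            + ", ".join(map(str, bad_rows)),
            bad_rows,
        )
    return CohortTable(records, provenance=str(path))


def _format_cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(cohort: CohortTable, path: str | Path, delimiter: str = ",") -> Path:
    """Write a cohort as delimited text; ``read_cohort`` round-trips it.

    Missing values serialize as empty cells.  Floats are written with full
    repr precision so the round-trip is bit-identical.
    """
    path = Path(path)
    extra_cols: list[str] = []
    for r in cohort.records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    header = list(SCHEMA_COLUMNS) + extra_cols
    lines = [delimiter.join(header)]
    for r in cohort.records:
        cells = [_format_cell(getattr(r, c)) for c in SCHEMA_COLUMNS]
        cells += [r.extra.get(c, "") for c in extra_cols]
        lines.append(delimiter.join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def load_schema_descriptor() -> dict:
    """The shipped JSON descriptor documenting every field, unit and level."""
    with resources.files("gksurv").joinpath("schema.json").open() as fh:
        return json.load(fh)
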