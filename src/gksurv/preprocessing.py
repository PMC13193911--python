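"""Fold-fitted imputation, one-hot encoding and engineered dose interactions.

The encoder is fitted on training rows only: numeric predictors get the
training median, categoricals the training mode (imputation happens before
encoding, so the mode level absorbs missingness), predictors with no observed
training values are dropped, and each kept categorical expands to indicator
columns for its non-reference levels.  Two engineered products of the
prescription dose with tumor volume and performance status are appended, and
they are recomputed from the (possibly counterfactual) dose at transform
time, which is what makes dose injection work downstream.

With the default predictor specification the encoded matrix has 28 columns:
nine numeric (seven measured variables plus the two dose interactions) and
nineteen level indicators.  Molecular fields whose source coding carries an
explicit "not available" pseudo-level emit an indicator for every substantive
level (no reference dropped); fully observed binaries and the two location
codings drop one reference level each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Sequence

import numpy as np

from .cohort import (
    ANATOMIC_LEVELS,
    CHR7P10Q_LEVELS,
    EGFR_LEVELS,
    MGMT_LEVELS,
    PTEN_LEVELS,
    SEX_LEVELS,
    TERT_LEVELS,
    TUMOR_LOC_LEVELS,
    CohortTable,
    LesionRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "EncoderState",
    "FeatureMatrix",
    "default_predictor_spec",
    "fit_encoder",
    "transform",
    "encode_record",
    "add_interactions",
]

DOSE_INTERACTION_COLUMNS = ("dose_x_vol", "dose_x_kps")


@dataclass(frozen=True)
class PredictorSpec:
    """Declaration of one predictor: its kind, levels, and reference level.

    ``reference=None`` for a categorical means every level is emitted as an
    indicator (used for fields whose source coding has an explicit missing
    pseudo-level, which is never emitted as a column).
    """

    name: str
    kind: str  # "num" | "cat"
    levels: tuple = ()
    reference: Optional[Any] = None

    def __post_init__(self) -> None:
        if self.kind not in ("num", "cat"):
            raise ValueError(f"kind must be 'num' or 'cat', got {self.kind!r}")
        if self.kind == "cat" and not self.levels:
            raise ValueError(f"categorical predictor {self.name} needs levels")
        if self.reference is not None and self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels of {self.name}"
            )


def default_predictor_spec() -> list[PredictorSpec]:
    """The full treatment-time + molecular predictor set (28 encoded columns)."""
    return [
        PredictorSpec("age_years", "num"),
        PredictorSpec("coverage", "num"),
        PredictorSpec("isodose_pct", "num"),
        PredictorSpec("max_gy", "num"),
        PredictorSpec("volume_cm3", "num"),
        PredictorSpec("dose_gy", "num"),
        PredictorSpec("kps", "num"),
        PredictorSpec("anatomic_loc", "cat", ANATOMIC_LEVELS, reference=1),
        PredictorSpec("chr7p10q", "cat", CHR7P10Q_LEVELS, reference="no"),
        PredictorSpec("egfr", "cat", EGFR_LEVELS, reference=None),
        PredictorSpec("mgmt", "cat", MGMT_LEVELS, reference=None),
        PredictorSpec("pten", "cat", PTEN_LEVELS, reference=None),
        PredictorSpec("sex", "cat", SEX_LEVELS, reference="F"),
        PredictorSpec("tert", "cat", TERT_LEVELS, reference=None),
        PredictorSpec("tumor_loc", "cat", TUMOR_LOC_LEVELS, reference=1),
    ]


@dataclass
class EncoderState:
    """Training-fold imputation/encoding parameters.

    Fitted exclusively on training rows; transforming any record yields
    exactly ``columns`` in order.
    """

    spec: list[PredictorSpec]
    medians: dict[str, float]
    modes: dict[str, Any]
    dropped: list[str]
    columns: list[str]
    with_interactions: bool

    def to_dict(self) -> dict:
        return {
            "spec": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "levels": list(s.levels),
                    "reference": s.reference,
                }
                for s in self.spec
            ],
            "medians": self.medians,
            "modes": self.modes,
            "dropped": self.dropped,
            "columns": self.columns,
            "with_interactions": self.with_interactions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderState":
        spec = [
            PredictorSpec(
                s["name"], s["kind"], tuple(s["levels"]), s["reference"]
            )
            for s in d["spec"]
        ]
        return cls(
            spec=spec,
            medians=dict(d["medians"]),
            modes=dict(d["modes"]),
            dropped=list(d["dropped"]),
            columns=list(d["columns"]),
            with_interactions=d["with_interactions"],
        )


@dataclass
class FeatureMatrix:
    """Fully numeric design matrix paired with the outcome arrays."""

    patient_ids: list[str]
    lesion_ids: list[str]
    columns: list[str]
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.X.shape != (len(self.patient_ids), len(self.columns)):
            raise ValueError("feature matrix shape inconsistent with keys/columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            [self.patient_ids[i] for i in idx],
            [self.lesion_ids[i] for i in idx],
            list(self.columns),
            self.X[idx],
            self.time[idx],
            self.event[idx],
        )


def add_interactions(dose_gy: float, volume_cm3: float, kps: float) -> tuple[float, float]:
    """Engineered dose interactions: (dose x volume, dose x KPS)."""
    return dose_gy * volume_cm3, dose_gy * kps


def fit_encoder(
    train: CohortTable | Sequence[LesionRecord],
    spec: Optional[Sequence[PredictorSpec]] = None,
    with_interactions: bool = True,
) -> EncoderState:
    """Fit imputation and encoding parameters on training rows only.

    Numeric medians and categorical modes are computed from observed training
    values; a predictor with zero observed training values is recorded as
    dropped and contributes no output columns.  Mode ties break by declared
    level order.  The dose interactions require dose, volume and KPS to be
    kept; if any of those is dropped, the interaction columns are dropped too.
    """
    records = list(train)
    if not records:
        raise ValueError("cannot fit an encoder on an empty training set")
    spec = list(spec) if spec is not None else default_predictor_spec()

    medians: dict[str, float] = {}
    modes: dict[str, Any] = {}
    dropped: list[str] = []
    columns: list[str] = []

    for s in spec:
        values = [getattr(r, s.name) for r in records]
        observed = [v for v in values if v is not None]
        if not observed:
            dropped.append(s.name)
            continue
        if s.kind == "num":
            medians[s.name] = float(np.median([float(v) for v in observed]))
            columns.append(s.name)
        else:
            counts = {lv: 0 for lv in s.levels}
            for v in observed:
                counts[v] += 1
            best = max(counts.values())
            modes[s.name] = next(lv for lv in s.levels if counts[lv] == best)
            for lv in s.levels:
                if s.reference is not None and lv == s.reference:
                    continue
                columns.append(f"{s.name}={lv}")

    emit_interactions = with_interactions and all(
        name in medians for name in ("dose_gy", "volume_cm3", "kps")
    )
    if with_interactions and not emit_interactions:
        dropped.extend(
            c for c in DOSE_INTERACTION_COLUMNS if c not in dropped
        )
    if emit_interactions:
        columns.extend(DOSE_INTERACTION_COLUMNS)

    return EncoderState(
        spec=spec,
        medians=medians,
        modes=modes,
        dropped=dropped,
        columns=columns,
        with_interactions=emit_interactions,
    )


def _encode_one(enc: EncoderState, record: LesionRecord) -> list[float]:
    row: list[float] = []
    imputed: dict[str, Any] = {}
    for s in enc.spec:
        if s.name in enc.dropped:
            continue
        value = getattr(record, s.name)
        if s.kind == "num":
            value = float(value) if value is not None else enc.medians[s.name]
            imputed[s.name] = value
            row.append(value)
        else:
            if value is None:
                value = enc.modes[s.name]
            elif value not in s.levels:
                logger.warning(
                    "unseen level %r for %s: encoding as all-zero indicators",
                    value,
                    s.name,
                )
            for lv in s.levels:
                if s.reference is not None and lv == s.reference:
                    continue
                row.append(1.0 if value == lv else 0.0)
    if enc.with_interactions:
        row.extend(
            add_interactions(
                imputed["dose_gy"], imputed["volume_cm3"], imputed["kps"]
            )
        )
    return row


def transform(
    enc: EncoderState, cohort: CohortTable | Iterable[LesionRecord]
) -> FeatureMatrix:
    """Map records through the fitted encoder to a numeric feature matrix.

    Pure and total on schema-valid records: numeric fields are median-imputed,
    categoricals mode-imputed then expanded to indicators, the dose
    interactions appended, and no missing values remain.
    """
    records = list(cohort)
    rows = [_encode_one(enc, r) for r in records]
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(enc.columns)))
    return FeatureMatrix(
        patient_ids=[r.patient_id for r in records],
        lesion_ids=[r.lesion_id for r in records],
        columns=list(enc.columns),
        X=X,
        time=np.array([r.time_months for r in records], dtype=float),
        event=np.array([r.event for r in records], dtype=int),
    )


def encode_record(enc: EncoderState, record: LesionRecord) -> np.ndarray:
    """Encode a single record to a 1-D feature row in ``enc.columns`` order."""
    return np.array(_encode_one(enc, record), dtype=float)
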