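"""Counterfactual dose sweep and prescription-dose recommendation.

For a single treated target the engine re-evaluates the fitted local-control
model across a clinically feasible grid of candidate prescription doses.
Each candidate is injected into the record: the prescription dose is
replaced, the dose interactions recompute automatically inside the encoder,
and the maximum dose is rederived from the dosimetric identity
``max = prescription / (isodose/100)`` while coverage is held fixed (no plan
re-optimization is modelled).  Candidates are scored by a predicted
local-control utility — probability of local control at 12 months, or the
expected local-control duration — and the recommendation takes the candidate
with the most favorable utility.  Within a configurable tie tolerance the
LOWEST dose wins, an explicit, auditable preference for sparing previously
irradiated brain when the model sees no meaningful gain from escalation.

Recommendations are decision support within the observed practice range, not
causal dose-response estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import LesionRecord
from .curves import SurvivalCurve
from .forest import SurvivalForest, predict_survival
from .outcomes import DEFAULT_HORIZONS, CaseSummary, summarize_curve
from .preprocessing import EncoderState, encode_record

__all__ = [
    "DoseGrid",
    "DoseSweepResult",
    "DoseRecommendation",
    "UTILITIES",
    "build_dose_grid",
    "inject_dose",
    "sweep_doses",
    "recommend",
    "export_candidates",
]

UTILITIES = ("lc_at_12m", "expected_lc")


@dataclass(frozen=True)
class DoseGrid:
    """Arithmetic sequence of candidate prescription doses (Gy)."""

    min_gy: float
    max_gy: float
    step_gy: float
    candidates: tuple[float, ...]


def build_dose_grid(min_gy: float, max_gy: float, step_gy: float = 0.5) -> DoseGrid:
    """Candidates {min, min+step, ...} not exceeding max."""
    if min_gy > max_gy:
        raise ValueError(f"inverted dose range: {min_gy} > {max_gy}")
    if step_gy <= 0:
        raise ValueError("step must be positive")
    n = int(math.floor((max_gy - min_gy) / step_gy + 1e-9)) + 1
    candidates = tuple(round(min_gy + i * step_gy, 10) for i in range(n))
    return DoseGrid(min_gy, max_gy, step_gy, candidates)


def inject_dose(
    record: LesionRecord, dose: float, enc: EncoderState, grid: Optional[DoseGrid] = None
) -> np.ndarray:
    """Encode the record under a counterfactual prescription dose.

    The record is copied with ``dose_gy := dose``; the maximum dose is
    recomputed through the isodose identity when the isodose line is known,
    and the dose interactions recompute inside the encoder.  Doses outside
    the feasible grid bounds are refused.
    """
    if grid is not None and not (grid.min_gy - 1e-9 <= dose <= grid.max_gy + 1e-9):
        raise ValueError(
            f"dose {dose} Gy outside the feasible range "
            f"[{grid.min_gy}, {grid.max_gy}] Gy"
        )
    if dose <= 0:
        raise ValueError("dose must be positive")
    changes: dict = {"dose_gy": dose}
    if record.isodose_pct is not None:
        changes["max_gy"] = dose / (record.isodose_pct / 100.0)
    return encode_record(enc, record.replace(**changes))


@dataclass
class DoseSweepResult:
    """Per-candidate utilities and summaries for one swept record."""

    patient_id: str
    lesion_id: str
    utility_name: str
    doses: list[float]
    utilities: list[float]
    summaries: list[CaseSummary]
    curves: list[SurvivalCurve]
    grid: DoseGrid


@dataclass
class DoseRecommendation:
    """Selected dose with its prediction bundle and the ranked candidates."""

    dose_gy: float
    summary: CaseSummary
    curve: SurvivalCurve
    ranked: list[tuple[float, float]]  # (dose, utility), utility desc / dose asc
    tie_note: str
    utility_name: str


def _utility(summary: CaseSummary, name: str) -> float:
    if name == "lc_at_12m":
        return summary.lc_at[12.0]
    if name == "expected_lc":
        return summary.expected_lc_months
    raise ValueError(f"unknown utility {name!r}; choose one of {UTILITIES}")


def sweep_doses(
    model: SurvivalForest,
    enc: EncoderState,
    record: LesionRecord,
    grid: DoseGrid,
    utility: str = "lc_at_12m",
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    tau: float = 18.0,
) -> DoseSweepResult:
    """Predict the local-control profile of every candidate dose for a case."""
    if utility not in UTILITIES:
        raise ValueError(f"unknown utility {utility!r}; choose one of {UTILITIES}")
    rows = np.vstack([inject_dose(record, d, enc, grid) for d in grid.candidates])
    curves = predict_survival(model, rows)
    summaries = [
        summarize_curve(c, horizons=horizons, tau=tau, dose_gy=d)
        for c, d in zip(curves, grid.candidates)
    ]
    utilities = [_utility(s, utility) for s in summaries]
    if not all(math.isfinite(u) for u in utilities):
        raise ValueError("non-finite utility in dose sweep")
    return DoseSweepResult(
        patient_id=record.patient_id,
        lesion_id=record.lesion_id,
        utility_name=utility,
        doses=list(grid.candidates),
        utilities=utilities,
        summaries=summaries,
        curves=curves,
        grid=grid,
    )


def recommend(sweep: DoseSweepResult, tie_tol: float = 0.005) -> DoseRecommendation:
    """Pick the lowest dose whose utility is within ``tie_tol`` of the best.

    The ranked table sorts by utility descending with ties broken by
    ascending dose; the recommendation is a pure function of the sweep.
    """
    if not sweep.doses:
        raise ValueError("empty dose sweep")
    best = max(sweep.utilities)
    eligible = [
        (d, u)
        for d, u in zip(sweep.doses, sweep.utilities)
        if u >= best - tie_tol
    ]
    rec_dose, rec_util = min(eligible)  # lowest dose among near-optimal
    idx = sweep.doses.index(rec_dose)
    ranked = sorted(
        zip(sweep.doses, sweep.utilities), key=lambda du: (-du[1], du[0])
    )
    if rec_util < best:
        note = (
            f"{rec_dose:g} Gy chosen over the utility maximum "
            f"({best:.4f}) within tie tolerance {tie_tol:g}"
        )
    else:
        note = "utility maximum attained at the recommended dose"
    return DoseRecommendation(
        dose_gy=rec_dose,
        summary=sweep.summaries[idx],
        curve=sweep.curves[idx],
        ranked=ranked,
        tie_note=note,
        utility_name=sweep.utility_name,
    )


def export_candidates(
    sweep: DoseSweepResult, rec: DoseRecommendation, path: str | Path
) -> Path:
    """Write the ranked candidate table and the recommended curve.

    The main file holds one row per candidate dose (utility, horizon
    probabilities, expected duration, recommended flag); a sibling
    ``*_curve.csv`` holds the (time, survival) pairs of the recommended
    curve.  Full repr precision is used so a reread matches in memory.
    """
    path = Path(path)
    horizons = sorted(sweep.summaries[0].lc_at)
    header = (
        ["dose_gy", "utility"]
        + [f"lc_at_{h:g}m" for h in horizons]
        + ["expected_lc_months", "recommended"]
    )
    lines = [",".join(header)]
    for d, u in rec.ranked:
        s = sweep.summaries[sweep.doses.index(d)]
        cells = [repr(float(d)), repr(float(u))]
        cells += [repr(float(s.lc_at[h])) for h in horizons]
        cells.append(repr(float(s.expected_lc_months)))
        cells.append("1" if d == rec.dose_gy else "0")
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")

    curve_path = path.with_name(path.stem + "_curve.csv")
    curve_lines = ["time_months,survival"]
    for t, s in zip(rec.curve.times, rec.curve.survival):
        curve_lines.append(f"{float(t)!r},{float(s)!r}")
    curve_path.write_text("\n".join(curve_lines) + "\n")
    return path
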