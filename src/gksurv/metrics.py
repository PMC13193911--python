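"""Discrimination and calibration metrics for right-censored predictions.

Implements Harrell's concordance index, the Kaplan-Meier estimate of the
censoring distribution, the inverse-probability-of-censoring-weighted (IPCW)
Brier score at a fixed horizon, and the integrated Brier score (IBS) averaged
over an evaluation window.  The censoring distribution used for weighting is
always estimated on training rows, never on the rows being scored — the
caller owns that split.

Conventions, used everywhere:

* Step functions evaluate right-continuously; the left limit G(t-) needed by
  the IPCW weights is taken from the jump bookkeeping, not via an epsilon.
* A pair (i, j) is comparable for the concordance index iff
  ``time_i < time_j`` strictly and subject i failed; tied event times are not
  comparable.  Tied risk scores earn half credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curves import SurvivalCurve

__all__ = [
    "StepFunction",
    "harrell_cindex",
    "km_censoring",
    "brier_score",
    "integrated_brier",
    "UndefinedMetricError",
    "WeightSingularityError",
]


class UndefinedMetricError(ValueError):
    """The metric has no comparable information in the supplied data."""


class WeightSingularityError(ValueError):
    """The censoring survival function vanished at a needed weight."""


@dataclass
class StepFunction:
    """Right-continuous step function with explicit jump bookkeeping."""

    jump_times: np.ndarray
    values: np.ndarray  # value attained at (and after) each jump
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_times.shape != self.values.shape or self.jump_times.ndim != 1:
            raise ValueError("jump_times and values must be 1-D of equal length")
        if self.jump_times.size and np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def _eval(self, t, side: str):
        t_arr = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            out = np.full(t_arr.shape, self.initial)
        else:
            idx = np.searchsorted(self.jump_times, t_arr, side=side) - 1
            out = np.where(
                idx >= 0, self.values[np.clip(idx, 0, None)], self.initial
            )
        return float(out) if t_arr.ndim == 0 else out

    def __call__(self, t) -> np.ndarray | float:
        return self._eval(t, "right")

    def left_limit(self, t) -> np.ndarray | float:
        """Value just before t: jumps at exactly t are excluded."""
        return self._eval(t, "left")


def harrell_cindex(
    times: np.ndarray, events: np.ndarray, risks: np.ndarray
) -> float:
    """Harrell's concordance index over comparable right-censored pairs.

    Raises :class:`UndefinedMetricError` when no pair is comparable (for
    instance, all-censored data).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if not (times.shape == events.shape == risks.shape):
        raise ValueError("times, events, risks must share a shape")

    # comparable pairs: i failed strictly before j's observed time
    comp = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs for the concordance index")
    gt = risks[:, None] > risks[None, :]
    eq = risks[:, None] == risks[None, :]
    concordant = float((comp & gt).sum()) + 0.5 * float((comp & eq).sum())
    return concordant / n_comp


def km_censoring(times: np.ndarray, events: np.ndarray) -> StepFunction:
    """Kaplan-Meier product-limit estimate of the censoring survival G(t).

    The event indicator is flipped: censored observations are the "events"
    whose distribution is being estimated, failures are treated as censored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    cens_sorted = 1 - events[order]

    uniq = np.unique(t_sorted[cens_sorted == 1])
    jumps = []
    vals = []
    g = 1.0
    for tc in uniq:
        n_at_risk = int(np.sum(t_sorted >= tc))
        d_cens = int(np.sum((t_sorted == tc) & (cens_sorted == 1)))
        g *= 1.0 - d_cens / n_at_risk
        jumps.append(tc)
        vals.append(g)
    return StepFunction(np.array(jumps), np.array(vals), initial=1.0)


def brier_score(
    t: float,
    curves: Sequence[SurvivalCurve],
    times: np.ndarray,
    events: np.ndarray,
    G: StepFunction,
) -> float:
    """IPCW Brier score of predicted survival at horizon ``t``.

    Subjects failing at or before ``t`` contribute S_i(t)^2 / G(T_i-);
    subjects still under observation past ``t`` contribute
    (1 - S_i(t))^2 / G(t); subjects censored at or before ``t`` contribute
    nothing.  The total is divided by n.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = times.size
    if n == 0 or len(curves) != n:
        raise ValueError("one predicted curve per subject is required")

    s_at_t = np.array([c.at(t) for c in curves])
    total = 0.0
    for i in range(n):
        if times[i] <= t and events[i] == 1:
            g = float(G.left_limit(times[i]))
            if g <= 0.0:
                raise WeightSingularityError(
                    f"censoring survival is 0 just before t={times[i]:g}"
                )
            total += s_at_t[i] ** 2 / g
        elif times[i] > t:
            g = float(G(t))
            if g <= 0.0:
                raise WeightSingularityError(
                    f"censoring survival is 0 at evaluation time t={t:g}"
                )
            total += (1.0 - s_at_t[i]) ** 2 / g
        # censored at or before t: weight 0
    return total / n


def integrated_brier(
    curves: Sequence[SurvivalCurve],
    times: np.ndarray,
    events: np.ndarray,
    G: StepFunction,
    tau: float,
    grid: np.ndarray | None = None,
) -> float:
    """Integrated Brier score (1/tau) * int_0^tau BS(t) dt.

    Integration is trapezoidal on the unique observed times within [0, tau]
    augmented with the endpoints; a custom ``grid`` may be supplied for
    convergence checks.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = np.asarray(times, dtype=float)
    if grid is None:
        inner = np.unique(times[(times > 0) & (times < tau)])
        grid = np.concatenate(([0.0], inner, [tau]))
    else:
        grid = np.asarray(grid, dtype=float)
    bs = np.array([brier_score(t, curves, times, events, G) for t in grid])
    return float(np.trapezoid(bs, grid) / tau)
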