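"""Piecewise-constant survival curves.

A :class:`SurvivalCurve` is the model-facing representation of predicted
local control: a right-continuous step function S(t) on a shared time grid,
with S(0) = 1 implicitly and previous-value evaluation between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurvivalCurve"]


@dataclass
class SurvivalCurve:
    """Step function of local-control probability over time (months)."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape or self.times.ndim != 1:
            raise ValueError("times and survival must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0,1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def at(self, t: float) -> float:
        """S(t) with the previous-grid-value (right-continuous step) convention.

        Before the first jump S is 1; past the last grid point the final
        value is carried forward.
        """
        if t < 0:
            raise ValueError(f"time must be non-negative, got {t}")
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def at_many(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("times must be non-negative")
        idx = np.searchsorted(self.times, ts, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out.astype(float)
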