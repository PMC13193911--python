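"""Optional matplotlib renderings of the pipeline outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .curves import SurvivalCurve
from .dose import DoseRecommendation, DoseSweepResult

__all__ = ["plot_lc_curve", "plot_dose_sweep", "plot_importance"]


def plot_lc_curve(curve: SurvivalCurve, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step([0.0, *curve.times], [1.0, *curve.survival], where="post")
    ax.set_xlabel("months since radiosurgery")
    ax.set_ylabel("local control probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_dose_sweep(
    sweep: DoseSweepResult, rec: DoseRecommendation, path: str | Path
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sweep.doses, sweep.utilities, marker="o", ms=3)
    ax.axvline(rec.dose_gy, color="tab:red", ls="--", label=f"recommended {rec.dose_gy:g} Gy")
    ax.set_xlabel("candidate prescription dose (Gy)")
    ax.set_ylabel(sweep.utility_name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_importance(deltas: dict[str, float], path: str | Path, top: int = 15) -> Path:
    items = sorted(deltas.items(), key=lambda kv: kv[1], reverse=True)[:top]
    names = [k for k, _ in items][::-1]
    vals = [v for _, v in items][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(items) + 1.5))
    ax.barh(names, vals)
    ax.set_xlabel("mean decrease in C-index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
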