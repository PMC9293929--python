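"""Standard figures for a closed-loop run.

Three panels mirror the usual artificial-pancreas report: glucose with
clinical zone bands and the reference, insulin infusion (commanded and
delivered), and the true meal disturbance against its on-line estimate.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engine import SimulationResult
from .metrics import ZoneThresholds

__all__ = ["plot_run"]


def plot_run(
    result: SimulationResult,
    out_dir: str | Path,
    stem: str | None = None,
    thresholds: ZoneThresholds = ZoneThresholds(),
) -> list[Path]:
    """Write glucose / insulin / disturbance PNGs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or result.scenario.label or "run"
    t_h = result.t / 60.0  # hours since 6 A.M.
    paths = []

    fig, ax = plt.subplots(figsize=(8, 4))
    top = max(200.0, float(result.G.max()) * 1.05)
    ax.axhspan(thresholds.hyper, top, color="tab:red", alpha=0.15, label="dangerous")
    ax.axhspan(thresholds.safe_upper, thresholds.hyper, color="tab:orange", alpha=0.15, label="warning")
    ax.axhspan(thresholds.hypo, thresholds.safe_upper, color="tab:green", alpha=0.15, label="safe")
    ax.axhspan(0, thresholds.hypo, color="tab:red", alpha=0.15)
    ax.plot(t_h, result.G, "k-", lw=1.2, label="G")
    ax.plot(t_h, result.G_d, "b--", lw=1.0, label="reference")
    ax.set(xlabel="time since 6 A.M. [h]", ylabel="blood glucose [mg/dl]", ylim=(40, top))
    ax.legend(loc="upper right", fontsize=8)
    p = out / f"{stem}_glucose.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t_h, result.u_commanded, lw=1.0, label="commanded u")
    if not (result.u_applied == result.u_commanded).all():
        ax.plot(t_h, result.u_applied, lw=1.0, ls="--", label="delivered u")
    ax.set(xlabel="time since 6 A.M. [h]", ylabel="insulin rate [uU/ml/min]")
    ax.legend(fontsize=8)
    p = out / f"{stem}_insulin.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t_h, result.D_true, lw=1.0, label="meal disturbance D")
    if result.scenario.mode == "adaptive":
        ax.plot(t_h, result.D_hat, lw=1.0, ls="--", label="estimate D_hat")
    ax.set(xlabel="time since 6 A.M. [h]", ylabel="glucose appearance [mg/dl/min]")
    ax.legend(fontsize=8)
    p = out / f"{stem}_disturbance.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
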