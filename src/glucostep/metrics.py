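"""Clinical zone classification and scalar glycemia summaries.

Zones on blood glucose [mg/dl]: below 70 hypoglycemia (dangerous),
70-130 safe, 130-180 warning, above 180 hyperglycemia (dangerous).
Boundaries 70 and 130 belong to the safe zone and 180 to the warning
zone, so every positive glucose value gets exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SimulationResult

__all__ = [
    "ZoneThresholds",
    "classify_zone",
    "peak_in_window",
    "time_to_zone",
    "recovery_time",
    "summarize",
]

ZONES = ("dangerous_low", "safe", "warning", "dangerous_high")


@dataclass(frozen=True)
class ZoneThresholds:
    hypo: float = 70.0
    safe_upper: float = 130.0
    hyper: float = 180.0

    def __post_init__(self) -> None:
        if not self.hypo < self.safe_upper < self.hyper:
            raise ValueError("thresholds must satisfy hypo < safe_upper < hyper")


def classify_zone(G: float, thresholds: ZoneThresholds = ZoneThresholds()) -> str:
    """Zone label for one glucose value; boundaries assigned inward (safer)."""
    if G <= 0:
        raise ValueError("glucose must be positive")
    if G < thresholds.hypo:
        return "dangerous_low"
    if G <= thresholds.safe_upper:
        return "safe"
    if G <= thresholds.hyper:
        return "warning"
    return "dangerous_high"


def peak_in_window(
    result: SimulationResult, t_from: float, t_to: float
) -> tuple[float, float]:
    """(max G, time of max) over report-grid times in [t_from, t_to]."""
    mask = (result.t >= t_from) & (result.t <= t_to)
    if not np.any(mask):
        raise ValueError("window contains no report-grid samples")
    Gw = result.G[mask]
    tw = result.t[mask]
    i = int(np.argmax(Gw))
    return float(Gw[i]), float(tw[i])


def time_to_zone(
    result: SimulationResult,
    zone: str,
    t_from: float = 0.0,
    thresholds: ZoneThresholds = ZoneThresholds(),
) -> float:
    """Minutes from t_from until glucose first lies in the requested zone."""
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {ZONES}")
    mask = result.t >= t_from
    for t, G in zip(result.t[mask], result.G[mask]):
        if classify_zone(float(G), thresholds) == zone:
            return float(t) - t_from
    raise ValueError(f"zone {zone!r} never reached after t={t_from} min")


def recovery_time(
    result: SimulationResult,
    t_event: float,
    band: float = 5.0,
    persistence: float = 10.0,
    search_window: float = 240.0,
) -> float:
    """Minutes from a disturbance event until glucose re-tracks the reference.

    The post-event peak is the maximum G within ``search_window`` minutes
    of ``t_event``; recovery is the first report-grid time after that
    peak at which |G - G_d| < ``band`` and remains below it for at least
    ``persistence`` consecutive minutes.  Returns 0 if tracking never
    left the band after the event.
    """
    if t_event < result.t[0] or t_event > result.t[-1]:
        raise ValueError("t_event outside the simulated horizon")
    dev = np.abs(result.G - result.G_d)
    after = result.t >= t_event
    if np.all(dev[after] < band):
        return 0.0
    _, t_peak = peak_in_window(
        result, t_event, min(t_event + search_window, float(result.t[-1]))
    )
    t = result.t
    inside = dev < band
    for i in np.nonzero((t >= t_peak) & inside)[0]:
        j = np.searchsorted(t, t[i] + persistence, side="right")
        if np.all(inside[i:j]):
            return float(t[i]) - t_event
    raise ValueError("glucose never re-entered the tracking band after the event")


def summarize(
    result: SimulationResult, thresholds: ZoneThresholds = ZoneThresholds()
) -> dict:
    """Flat key-value glycemia summary for one run (serialisable to JSON)."""
    labels = np.array([classify_zone(float(g), thresholds) for g in result.G])
    frac = {z: float(np.mean(labels == z)) for z in ZONES}
    peak, t_peak = peak_in_window(result, float(result.t[0]), float(result.t[-1]))
    worst = max(labels, key=lambda z: ZONES.index(z) if z != "dangerous_low" else 3)
    return {
        "G_max": peak,
        "t_G_max": t_peak,
        "G_min": float(np.min(result.G)),
        "G_final": float(result.G[-1]),
        "mean_abs_tracking_error": float(np.mean(np.abs(result.G - result.G_d))),
        "worst_zone": str(worst),
        **{f"fraction_{z}": frac[z] for z in ZONES},
    }
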