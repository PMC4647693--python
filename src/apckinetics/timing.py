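"""Degradation-timing metrics: T95, T50, Td and APC/C occupancy.

T95 — time from APC/C-Cdc20 activation (t = 0) until total substrate falls
to 95 % of its initial amount; the model's proxy for the delay in
degradation onset. Td = T50 - T95, the time to go from 95 % to 50 %
remaining; the proxy for degradation rate. Crossings are located by linear
interpolation between output samples and are *censored* (None) when the
level is never reached within the simulated horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TimeCourse
from .parameters import MAX_UB


@dataclass(frozen=True)
class TimingMetrics:
    """Timing summary of one substrate's degradation curve.

    ``None`` fields mark censored quantities (crossing not reached within
    the horizon).
    """

    T95: float | None
    T50: float | None
    Td: float | None
    max_occupancy: float | None

    @property
    def censored(self) -> bool:
        return self.T95 is None or self.T50 is None


def substrate_species(label: str = "S") -> tuple[str, ...]:
    """All species names carrying substrate ``label`` (free and bound)."""
    return tuple(f"{label}{i}" for i in range(MAX_UB + 1)) + tuple(
        f"A{label}{i}" for i in range(MAX_UB + 1)
    )


def total_substrate(tc: TimeCourse, label: str = "S") -> np.ndarray:
    """Total substrate (free + APC/C-bound, all ubiquitin counts), nM."""
    return tc.group(substrate_species(label))


def crossing_time(times: np.ndarray, series: np.ndarray, fraction: float) -> float | None:
    """First time the series reaches ``fraction`` of its initial value.

    Linear interpolation between samples; ``None`` if the level is never
    reached. The baseline is the t=0 value, not the running maximum.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    baseline = series[0]
    if baseline <= 0:
        raise ValueError("series starts at zero: crossing fraction undefined")
    level = fraction * baseline
    below = series <= level
    if not below.any():
        return None
    j = int(np.argmax(below))  # first index at or below the level
    if j == 0:
        return float(times[0])
    t0, t1 = times[j - 1], times[j]
    v0, v1 = series[j - 1], series[j]
    if v0 == v1:
        return float(t1)
    return float(t0 + (v0 - level) / (v0 - v1) * (t1 - t0))


def max_occupancy(tc: TimeCourse, label: str = "S") -> float | None:
    """Maximum fraction of total APC/C-Cdc20 bound to substrate ``label``.

    Total APC/C at time t is free A plus every bound complex (any substrate).
    Time points where total APC/C is zero are skipped; ``None`` if it is zero
    throughout.
    """
    bound_labels = [n for n in tc.species if n.startswith("A") and n != "A"]
    total_apc = tc["A"] + tc.group(bound_labels)
    mine = tc.group([f"A{label}{i}" for i in range(MAX_UB + 1)])
    ok = total_apc > 0
    if not ok.any():
        return None
    return float(np.max(mine[ok] / total_apc[ok]))


def compute_timing_metrics(tc: TimeCourse, label: str = "S") -> TimingMetrics:
    """T95, T50, Td and peak occupancy for one substrate in a time course."""
    series = total_substrate(tc, label)
    t95 = crossing_time(tc.times, series, 0.95)
    t50 = crossing_time(tc.times, series, 0.50)
    td = None if (t95 is None or t50 is None) else t50 - t95
    return TimingMetrics(T95=t95, T50=t50, Td=td, max_occupancy=max_occupancy(tc, label))
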