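"""Log-spaced parameter grids, metric maps, region masks and sensitivity.

The default grid evaluates 25 values each of the catalytic rate constant
k_c and the dissociation rate constant k_d, log-spaced on [1e-3, 1e3]/s
(neighbor ratio 10^(6/24) = 10^0.25, commonly rounded to "a factor of
1.8"), and six values of the association rate constant k_a on [1e-4, 10]
per (nM s) (neighbor ratio 10).

Region masks encode the two in-vivo-motivated timing criteria: a delayed
degradation onset (T95 > 200 s) and a fast degradation rate (Td < 600 s);
their overlap is the small parameter zone where both hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import IntegrationError, simulate
from .parameters import RateParameters, TwoSubstrateParameters
from .competition import run_competition
from .timing import compute_timing_metrics

#: exact grid neighbor ratio for k_c / k_d; the rounded "factor of 1.8"
STEP_FACTOR = 10.0 ** 0.25

T95_THRESHOLD_S = 200.0   # delayed-onset criterion: T95 > 200 s
TD_THRESHOLD_S = 600.0    # fast-degradation criterion: Td < 600 s


@dataclass(frozen=True)
class LogGrid:
    """Log-spaced evaluation grid over (k_c, k_d[, k_a])."""

    k_c: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 25))
    k_d: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 25))
    k_a: np.ndarray = field(default_factory=lambda: np.logspace(-4, 1, 6))

    def cells(self, k_a: float | None = None):
        """Iterate (k_a, k_c, k_d) triples; a fixed k_a narrows to one slice."""
        ka_values = self.k_a if k_a is None else np.asarray([k_a])
        for ka in ka_values:
            for kc in self.k_c:
                for kd in self.k_d:
                    yield float(ka), float(kc), float(kd)


def build_grid(
    k_c_range: tuple[float, float] = (1e-3, 1e3),
    n_k_c: int = 25,
    k_d_range: tuple[float, float] = (1e-3, 1e3),
    n_k_d: int = 25,
    k_a_range: tuple[float, float] = (1e-4, 10.0),
    n_k_a: int = 6,
) -> LogGrid:
    """Build a log-spaced grid with exact endpoint inclusion."""
    for lo, hi in (k_c_range, k_d_range, k_a_range):
        if lo <= 0 or hi <= lo:
            raise ValueError("grid ranges must be positive with hi > lo")
    return LogGrid(
        k_c=np.logspace(np.log10(k_c_range[0]), np.log10(k_c_range[1]), n_k_c),
        k_d=np.logspace(np.log10(k_d_range[0]), np.log10(k_d_range[1]), n_k_d),
        k_a=np.logspace(np.log10(k_a_range[0]), np.log10(k_a_range[1]), n_k_a),
    )


@dataclass
class ScanResult:
    """Per-cell metric table plus named boolean masks and provenance."""

    grid: LogGrid
    table: pd.DataFrame
    provenance: dict

    def mask(self, name: str) -> pd.Series:
        """Named region mask over the table rows.

        ``delay``: T95 > 200 s; ``rate``: Td < 600 s; ``overlap``: both.
        Censored cells are False in every mask.
        """
        t = self.table
        t95 = t["T95"].to_numpy(dtype=float)
        td = t["Td"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            delay = np.nan_to_num(t95, nan=-np.inf) > T95_THRESHOLD_S
            rate = np.nan_to_num(td, nan=np.inf) < TD_THRESHOLD_S
        if name == "delay":
            values = delay
        elif name == "rate":
            values = rate
        elif name == "overlap":
            values = delay & rate
        else:
            raise KeyError(f"unknown mask {name!r}")
        return pd.Series(values, index=t.index, name=name)


def _metrics_row(metrics) -> dict:
    return {
        "T95": np.nan if metrics.T95 is None else metrics.T95,
        "T50": np.nan if metrics.T50 is None else metrics.T50,
        "Td": np.nan if metrics.Td is None else metrics.Td,
        "max_occupancy": (np.nan if metrics.max_occupancy is None
                          else metrics.max_occupancy),
        "censored": metrics.censored,
    }


def scan(
    grid: LogGrid,
    base_params: RateParameters = RateParameters(),
    k_a: float | None = 0.01,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
) -> ScanResult:
    """One-substrate scan: simulate every grid cell and tabulate metrics.

    A per-cell solver failure is recorded (``solver_ok=False``) without
    aborting the rest of the scan. Deterministic: identical settings give
    identical tables.
    """
    rows = []
    for ka, kc, kd in grid.cells(k_a=k_a):
        row = {"k_a": ka, "k_c": kc, "k_d": kd, "solver_ok": True}
        params = base_params.with_(k_a=ka, k_c=kc, k_d=kd)
        try:
            tc = simulate(params, horizon=horizon, output_grid=output_grid)
            row.update(_metrics_row(compute_timing_metrics(tc)))
        except IntegrationError:
            row.update(T95=np.nan, T50=np.nan, Td=np.nan,
                       max_occupancy=np.nan, censored=True, solver_ok=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    provenance = {
        "model": "one_substrate",
        "base_params": base_params.to_dict(),
        "k_a_fixed": k_a,
        "horizon_s": horizon,
        "output_grid_s": output_grid,
    }
    return ScanResult(grid=grid, table=table, provenance=provenance)


def scan_two_substrate(
    grid: LogGrid,
    scenario: str,
    base: TwoSubstrateParameters = TwoSubstrateParameters(),
    k_a: float = 0.01,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
    cells: pd.DataFrame | None = None,
) -> ScanResult:
    """Two-substrate scan indexed by S's (k_c, k_d); C follows the scenario.

    ``cells`` optionally restricts evaluation to given (k_c, k_d) pairs
    (columns ``k_c``, ``k_d``) instead of the full grid.
    """
    if scenario == "affinity":
        make = TwoSubstrateParameters.affinity
    elif scenario == "catalytic":
        make = TwoSubstrateParameters.catalytic
    else:
        raise ValueError(f"scenario must be 'affinity' or 'catalytic', got {scenario!r}")
    shared = dict(k_a=k_a, e=base.e, p_A=base.p_A, A_const=base.A_const,
                  S_init=base.S_init, C_init=base.C_init, apc_mode=base.apc_mode)
    if cells is None:
        pairs = [(kc, kd) for _, kc, kd in grid.cells(k_a=k_a)]
    else:
        pairs = list(zip(cells["k_c"], cells["k_d"]))

    rows = []
    for kc, kd in pairs:
        row = {"k_a": k_a, "k_c": kc, "k_d": kd, "solver_ok": True}
        params = make(k_c_S=kc, k_d_S=kd, **shared)
        try:
            _, cm = run_competition(params, horizon=horizon, output_grid=output_grid)
            mS, mC = cm.metrics_S, cm.metrics_C
            row.update({
                "T95_S": np.nan if mS.T95 is None else mS.T95,
                "Td_S": np.nan if mS.Td is None else mS.Td,
                "T95_C": np.nan if mC.T95 is None else mC.T95,
                "Td_C": np.nan if mC.Td is None else mC.Td,
                "rel_onset_difference": (np.nan if cm.rel_onset_difference is None
                                         else cm.rel_onset_difference),
                "td_ratio": np.nan if cm.td_ratio is None else cm.td_ratio,
                "competition_effect": (np.nan if cm.competition_effect is None
                                       else cm.competition_effect),
                "max_occupancy_S": (np.nan if cm.max_occupancy_S is None
                                    else cm.max_occupancy_S),
                "max_occupancy_C": (np.nan if cm.max_occupancy_C is None
                                    else cm.max_occupancy_C),
                "censored": mS.censored or mC.censored,
            })
        except IntegrationError:
            row.update(censored=True, solver_ok=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    provenance = {
        "model": "two_substrate",
        "scenario": scenario,
        "shared": shared,
        "horizon_s": horizon,
        "output_grid_s": output_grid,
    }
    return ScanResult(grid=grid, table=table, provenance=provenance)


def sensitivity(
    params: RateParameters,
    which: str,
    factor: float = STEP_FACTOR,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
) -> float | None:
    """Relative decrease of T95 under a one-step rate perturbation.

    ``which="k_c_up"`` multiplies k_c by ``factor``; ``which="k_d_down"``
    divides k_d by ``factor``. The perturbed run is recomputed from scratch
    (valid off-grid too). Returns (T95_base - T95_perturbed) / T95_base, or
    ``None`` when either run is censored.
    """
    if which == "k_c_up":
        perturbed = params.with_(k_c=params.k_c * factor)
    elif which == "k_d_down":
        perturbed = params.with_(k_d=params.k_d / factor)
    else:
        raise ValueError("which must be 'k_c_up' or 'k_d_down'")
    base_m = compute_timing_metrics(simulate(params, horizon=horizon,
                                             output_grid=output_grid))
    if base_m.T95 is None or base_m.T95 == 0:
        return None
    pert_m = compute_timing_metrics(simulate(perturbed, horizon=horizon,
                                             output_grid=output_grid))
    if pert_m.T95 is None:
        return None
    return (base_m.T95 - pert_m.T95) / base_m.T95
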