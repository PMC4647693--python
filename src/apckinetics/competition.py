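"""Two substrates, S and C, competing for a single APC/C-Cdc20 pool.

The reaction set duplicates the one-substrate model for C (species C0..C4,
AC0..AC4) with its own dissociation and catalytic rate constants; both
substrates bind the shared free-APC/C pool with the same association rate
constant. Competition arises only through that shared pool — there is no
direct S-C interaction.

Metrics compare the two substrates and quantify the competition effect:

- ``rel_onset_difference`` = (T95_S - T95_C) / T95_C — how much later S's
  degradation starts relative to C's.
- ``td_ratio`` = Td_C / Td_S — C degrades faster when the ratio is below 1.
- ``competition_effect`` = (T95_S[two-substrate] - T95_S[alone]) /
  T95_S[alone] — the delay C imposes on S by sequestering APC/C, with the
  one-substrate run of S (same parameters) as the baseline.

Any metric whose inputs are censored (crossing not reached within the
horizon) is itself censored, never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    CLIP_NM,
    IntegrationError,
    TimeCourse,
    euler_integrate,
    simulate,
    _output_times,
)
from .parameters import TwoSubstrateParameters
from .timing import compute_timing_metrics, TimingMetrics

SPECIES_TWO = (
    ("A",)
    + tuple(f"S{i}" for i in range(5))
    + tuple(f"AS{i}" for i in range(5))
    + tuple(f"C{i}" for i in range(5))
    + tuple(f"AC{i}" for i in range(5))
)


@dataclass(frozen=True)
class CompetitionMetrics:
    rel_onset_difference: float | None
    td_ratio: float | None
    competition_effect: float | None
    max_occupancy_S: float | None
    max_occupancy_C: float | None
    metrics_S: TimingMetrics = None
    metrics_C: TimingMetrics = None
    metrics_S_alone: TimingMetrics = None


def initial_state_two(params: TwoSubstrateParameters) -> np.ndarray:
    y0 = np.zeros(len(SPECIES_TWO))
    if params.apc_mode == "constant":
        y0[0] = params.A_const
    y0[1] = params.S_init
    y0[11] = params.C_init
    return y0


def _rhs_closure_two(params: TwoSubstrateParameters):
    ka, e = params.k_a, params.e
    kdS, kcS = params.k_d_S, params.k_c_S
    kdC, kcC = params.k_d_C, params.k_c_C
    pA = params.p_A if params.apc_mode == "linear" else 0.0

    def rhs(t, y):
        A = y[0]
        S, AS = y[1:6], y[6:11]
        C, AC = y[11:16], y[16:21]

        bS = ka * A * S
        dSdis = kdS * AS
        cS = kcS * AS[:4]
        bC = ka * A * C
        dCdis = kdC * AC
        cC = kcC * AC[:4]

        dS = dSdis - bS
        dAS = bS - dSdis
        dAS[:4] -= cS
        dAS[1:] += cS
        dS[4] -= e * S[4]
        dAS[4] -= e * AS[4]

        dC = dCdis - bC
        dAC = bC - dCdis
        dAC[:4] -= cC
        dAC[1:] += cC
        dC[4] -= e * C[4]
        dAC[4] -= e * AC[4]

        dy = np.empty(21)
        dy[0] = (pA - bS.sum() - bC.sum() + dSdis.sum() + dCdis.sum()
                 + e * (AS[4] + AC[4]))
        dy[1:6] = dS
        dy[6:11] = dAS
        dy[11:16] = dC
        dy[16:21] = dAC
        return dy

    return rhs


def derivatives_two_substrate(state: np.ndarray, params: TwoSubstrateParameters) -> np.ndarray:
    """Mass-action rates (nM/s) for the 21-species two-substrate system."""
    return _rhs_closure_two(params)(0.0, np.asarray(state, dtype=float))


def simulate_two_substrate(
    params: TwoSubstrateParameters,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "adaptive",
    dt: float = 1e-3,
) -> TimeCourse:
    """Integrate the two-substrate model; same conventions as ``simulate``."""
    times = _output_times(horizon, output_grid)
    y0 = initial_state_two(params)
    if method == "fixed":
        states = euler_integrate(_rhs_closure_two(params), y0, times, dt)
    else:
        sol = solve_ivp(
            _rhs_closure_two(params), (0.0, times[-1]), y0,
            method="LSODA", t_eval=times, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}", params)
        states = sol.y.T.copy()
    states[np.abs(states) < CLIP_NM] = 0.0
    states = np.maximum(states, 0.0)
    return TimeCourse(times=times, states=states, species=SPECIES_TWO, params=params)


def _ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or den == 0:
        return None
    return num / den


def run_competition(
    params: TwoSubstrateParameters,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
) -> tuple[TimeCourse, CompetitionMetrics]:
    """Simulate the two-substrate system and its one-substrate S baseline.

    Returns the two-substrate time course together with the comparison
    metrics; censoring propagates into every derived ratio.
    """
    tc = simulate_two_substrate(params, horizon=horizon, output_grid=output_grid)
    mS = compute_timing_metrics(tc, "S")
    mC = compute_timing_metrics(tc, "C")
    tc_alone = simulate(params.substrate_params("S"), horizon=horizon,
                        output_grid=output_grid)
    mS_alone = compute_timing_metrics(tc_alone, "S")

    rel_onset = None
    if mS.T95 is not None and mC.T95 is not None and mC.T95 > 0:
        rel_onset = (mS.T95 - mC.T95) / mC.T95
    td_ratio = _ratio(mC.Td, mS.Td)
    comp_effect = None
    if mS.T95 is not None and mS_alone.T95 is not None and mS_alone.T95 > 0:
        comp_effect = (mS.T95 - mS_alone.T95) / mS_alone.T95

    metrics = CompetitionMetrics(
        rel_onset_difference=rel_onset,
        td_ratio=td_ratio,
        competition_effect=comp_effect,
        max_occupancy_S=mS.max_occupancy,
        max_occupancy_C=mC.max_occupancy,
        metrics_S=mS,
        metrics_C=mC,
        metrics_S_alone=mS_alone,
    )
    return tc, metrics
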