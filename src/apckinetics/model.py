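"""One-substrate mass-action model of multi-step APC/C-Cdc20 ubiquitination.

Species (nM): free APC/C-Cdc20 ``A``; free substrate with i ubiquitins
``S0..S4``; APC/C-bound substrate with i ubiquitins ``AS0..AS4``.

Reactions (all mass action):

- binding       A + Si  -> ASi        rate k_a * A * Si   (all i, incl. i=4)
- dissociation  ASi     -> A + Si     rate k_d * ASi
- catalysis     ASi     -> ASi+1      rate k_c * ASi      (i < 4)
- degradation   S4 -> 0, AS4 -> A     rate e * (S4 or AS4)
- deubiquitination (optional)         one ubiquitin removed per event at
                                      rate k_dub on the variant's species
- APC/C input   0 -> A at rate p_A (linear mode) or A(0)=A_const (constant)

Degradation of AS4 releases free APC/C: the enzyme is not consumed. There is
no substrate production, so total substrate can only fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import MAX_UB, RateParameters

SPECIES_ONE = ("A", "S0", "S1", "S2", "S3", "S4", "AS0", "AS1", "AS2", "AS3", "AS4")

#: concentrations closer to zero than this (from solver round-off) are
#: reported as exactly zero
CLIP_NM = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails for a given parameter set."""

    def __init__(self, message: str, params=None):
        super().__init__(message if params is None else f"{message} (params={params})")
        self.params = params


@dataclass(frozen=True)
class TimeCourse:
    """Solution of a kinetic model sampled on a uniform output grid.

    ``states`` has one row per time point, columns ordered as ``species``.
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple
    params: object

    def __post_init__(self):
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states shape does not match times x species")

    def index(self, name: str) -> int:
        return self.species.index(name)

    def __getitem__(self, name: str) -> np.ndarray:
        """Concentration trace of one species, nM."""
        return self.states[:, self.index(name)]

    def group(self, prefix_names) -> np.ndarray:
        """Sum of the named species at every time point."""
        idx = [self.index(n) for n in prefix_names]
        return self.states[:, idx].sum(axis=1)


def initial_state(params: RateParameters) -> np.ndarray:
    y0 = np.zeros(len(SPECIES_ONE))
    if params.apc_mode == "constant":
        y0[0] = params.A_const
    y0[1] = params.S0_init
    return y0


def _deub_masks(variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-ubiquitin-count masks (i=1..4) for free and bound species."""
    free = np.zeros(MAX_UB)
    bound = np.zeros(MAX_UB)
    if variant == "all":
        free[:] = 1.0
        bound[:] = 1.0
    elif variant == "free_only":
        free[:] = 1.0
    elif variant == "bound_only":
        bound[:] = 1.0
    elif variant == "mono_only":
        free[0] = 1.0
        bound[0] = 1.0
    return free, bound


def derivatives_one_substrate(state: np.ndarray, params: RateParameters) -> np.ndarray:
    """Mass-action rate of change (nM/s) for every species.

    ``state`` is ordered as :data:`SPECIES_ONE`.
    """
    y = np.asarray(state, dtype=float)
    A = y[0]
    S = y[1:6]
    AS = y[6:11]

    bind = params.k_a * A * S          # A + Si -> ASi
    diss = params.k_d * AS             # ASi -> A + Si
    cat = params.k_c * AS[:MAX_UB]     # ASi -> ASi+1

    dS = -bind + diss
    dAS = bind - diss
    dAS[:MAX_UB] -= cat
    dAS[1:] += cat

    # proteasomal degradation of four-ubiquitin species
    dS[MAX_UB] -= params.e * S[MAX_UB]
    dAS[MAX_UB] -= params.e * AS[MAX_UB]

    dA = -bind.sum() + diss.sum() + params.e * AS[MAX_UB]
    if params.apc_mode == "linear":
        dA += params.p_A

    if params.deub_variant != "none" and params.k_dub > 0:
        mfree, mbound = _deub_masks(params.deub_variant)
        df = params.k_dub * mfree * S[1:]     # Si -> Si-1
        db = params.k_dub * mbound * AS[1:]   # ASi -> ASi-1
        dS[1:] -= df
        dS[:MAX_UB] += df
        dAS[1:] -= db
        dAS[:MAX_UB] += db

    out = np.empty_like(y)
    out[0] = dA
    out[1:6] = dS
    out[6:11] = dAS
    return out


def _rhs_closure(params: RateParameters):
    """Allocation-light RHS bound to a parameter set, for the solver."""
    ka, kd, kc, e = params.k_a, params.k_d, params.k_c, params.e
    pA = params.p_A if params.apc_mode == "linear" else 0.0
    kdub = params.k_dub if params.deub_variant != "none" else 0.0
    mfree, mbound = _deub_masks(params.deub_variant)
    use_deub = kdub > 0 and (mfree.any() or mbound.any())

    def rhs(t, y):
        A = y[0]
        S = y[1:6]
        AS = y[6:11]
        bind = ka * A * S
        diss = kd * AS
        cat = kc * AS[:4]
        dS = diss - bind
        dAS = bind - diss
        dAS[:4] -= cat
        dAS[1:] += cat
        dS[4] -= e * S[4]
        dAS[4] -= e * AS[4]
        if use_deub:
            df = kdub * mfree * S[1:]
            db = kdub * mbound * AS[1:]
            dS[1:] -= df
            dS[:4] += df
            dAS[1:] -= db
            dAS[:4] += db
        dy = np.empty(11)
        dy[0] = pA - bind.sum() + diss.sum() + e * AS[4]
        dy[1:6] = dS
        dy[6:11] = dAS
        return dy

    return rhs


def _output_times(horizon: float, output_grid: float) -> np.ndarray:
    n = int(round(horizon / output_grid))
    return np.linspace(0.0, n * output_grid, n + 1)


def simulate(
    params: RateParameters,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "adaptive",
    dt: float = 1.0,
) -> TimeCourse:
    """Integrate the one-substrate model over ``[0, horizon]`` seconds.

    The default integrator is an adaptive stiff-capable solver (LSODA);
    the large degradation rate constant (e = 1000/s by default) makes the
    system stiff. ``method="fixed"`` instead runs explicit forward Euler
    at step ``dt`` — a transparent replication/oracle mode; ``dt`` must then
    be small enough for stability (dt < 2/e).

    Reported concentrations are clipped to zero below :data:`CLIP_NM`.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if output_grid <= 0 or output_grid > horizon:
        raise ValueError("output_grid must be in (0, horizon]")
    times = _output_times(horizon, output_grid)
    y0 = initial_state(params)

    if method == "fixed":
        states = euler_integrate(_rhs_closure(params), y0, times, dt)
    elif method == "adaptive":
        sol = solve_ivp(
            _rhs_closure(params), (0.0, times[-1]), y0,
            method="LSODA", t_eval=times, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}", params)
        states = sol.y.T.copy()
    else:
        raise ValueError(f"unknown method {method!r}")

    states[np.abs(states) < CLIP_NM] = 0.0
    states = np.maximum(states, 0.0)
    return TimeCourse(times=times, states=states, species=SPECIES_ONE, params=params)


def euler_integrate(rhs, y0: np.ndarray, output_times: np.ndarray, dt: float) -> np.ndarray:
    """Fixed-step explicit Euler, sampled at ``output_times``.

    Independent of the adaptive path: a plain first-order update
    ``y <- y + dt * f(t, y)``. ``dt`` must (approximately) divide the output
    spacing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spacing = np.diff(output_times)
    steps_per_out = spacing / dt
    n_steps = np.rint(steps_per_out).astype(int)
    if not np.allclose(steps_per_out, n_steps, rtol=1e-9, atol=1e-9):
        raise ValueError("dt must divide the output grid spacing")
    y = np.array(y0, dtype=float)
    out = np.empty((output_times.size, y.size))
    out[0] = y
    t = output_times[0]
    for k, n in enumerate(n_steps, start=1):
        for _ in range(int(n)):
            y = y + dt * rhs(t, y)
            t += dt
        out[k] = y
    return out


def euler_reference(
    params: RateParameters,
    horizon: float = 3000.0,
    output_grid: float = 1.0,
    dt: float = 1e-3,
) -> TimeCourse:
    """Fixed-step Euler reference solution (oracle for the adaptive solver)."""
    times = _output_times(horizon, output_grid)
    states = euler_integrate(_rhs_closure(params), initial_state(params), times, dt)
    states[np.abs(states) < CLIP_NM] = 0.0
    states = np.maximum(states, 0.0)
    return TimeCourse(times=times, states=states, species=SPECIES_ONE, params=params)
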