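"""Seeded synthetic single-cell fluorescence traces.

Emulates GFP-degradation traces as acquired in live-cell imaging: a flat
plateau while the substrate is stable, then a decline (exponential, or the
total-substrate output of a kinetic model run), sampled every 30 s over a
one-hour session, with additive Gaussian noise and per-cell jitter of the
onset time. Every trace is reproducible from (seed, cell_index) alone.

Noise is additive Gaussian only; photobleaching and background drift are
not modelled, so detector tests on these traces probe noise robustness,
not illumination artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TimeCourse, simulate
from .onset import FluorescenceTrace
from .parameters import RateParameters
from .timing import total_substrate


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Recipe for a population of synthetic degradation traces.

    ``decline`` is either ``("exponential", rate_per_s)`` or
    ``("model", TimeCourse)``; in model mode the post-onset shape follows
    the normalized total-substrate curve of the time course.
    """

    plateau: float = 1000.0          # a.u.
    onset_s: float = 600.0           # mean onset time
    decline: tuple = ("exponential", 0.005)
    noise_sd_frac: float = 0.02      # noise SD as a fraction of the plateau
    sampling_s: float = 30.0
    duration_s: float = 3600.0
    n_cells: int = 30
    onset_jitter_sd_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.plateau <= 0 or self.sampling_s <= 0 or self.duration_s <= 0:
            raise ValueError("plateau, sampling and duration must be positive")
        if self.onset_s < 0 or self.noise_sd_frac < 0 or self.onset_jitter_sd_s < 0:
            raise ValueError("onset, noise and jitter must be non-negative")
        if self.onset_s + 5 * self.sampling_s >= self.duration_s:
            raise ValueError("onset too late: need >= 5 samples of decline")
        kind = self.decline[0]
        if kind not in ("exponential", "model"):
            raise ValueError(f"unknown decline kind {kind!r}")


def _decline_curve(spec: TraceGeneratorSpec, t_after_onset: np.ndarray) -> np.ndarray:
    """Normalized (starts at 1) decline evaluated at times past onset."""
    kind = spec.decline[0]
    if kind == "exponential":
        rate = float(spec.decline[1])
        return np.exp(-rate * t_after_onset)
    tc: TimeCourse = spec.decline[1]
    series = total_substrate(tc)
    if series[0] <= 0:
        raise ValueError("model decline needs a positive initial substrate")
    return np.interp(t_after_onset, tc.times, series / series[0])


def _rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cell_index]))


def generate_trace(spec: TraceGeneratorSpec, cell_index: int) -> FluorescenceTrace:
    """One synthetic trace: plateau, then decline, plus i.i.d. noise.

    The recorded ``true_onset`` includes the per-cell jitter, so it is the
    exact time the noiseless curve starts declining.
    """
    rng = _rng(spec.seed, cell_index)
    onset = spec.onset_s
    if spec.onset_jitter_sd_s > 0:
        onset = max(0.0, onset + rng.normal(0.0, spec.onset_jitter_sd_s))
    times = np.arange(0.0, spec.duration_s + 0.5 * spec.sampling_s, spec.sampling_s)
    clean = np.full(times.size, spec.plateau)
    after = times >= onset
    clean[after] = spec.plateau * _decline_curve(spec, times[after] - onset)
    noisy = clean
    if spec.noise_sd_frac > 0:
        noisy = clean + rng.normal(0.0, spec.noise_sd_frac * spec.plateau, times.size)
    return FluorescenceTrace(cell_id=f"cell_{cell_index:04d}", times=times,
                             intensities=noisy, true_onset=float(onset))


def generate_population(spec: TraceGeneratorSpec) -> list[FluorescenceTrace]:
    """``n_cells`` traces, each independently seeded from (seed, index)."""
    return [generate_trace(spec, i) for i in range(spec.n_cells)]


def generate_model_population(
    params: RateParameters,
    spec: TraceGeneratorSpec,
    horizon: float = 3000.0,
) -> list[FluorescenceTrace]:
    """Traces whose decline follows a kinetic-model total-substrate curve.

    Bridges simulation and detection: the model is integrated once, its
    total-substrate output becomes the post-onset shape (scaled to the
    plateau), and noise/sampling/jitter follow ``spec``. With a flat model
    output (e.g. k_c = 0) the traces never decline.
    """
    tc = simulate(params, horizon=horizon, output_grid=1.0)
    model_spec = TraceGeneratorSpec(
        plateau=spec.plateau, onset_s=spec.onset_s, decline=("model", tc),
        noise_sd_frac=spec.noise_sd_frac, sampling_s=spec.sampling_s,
        duration_s=spec.duration_s, n_cells=spec.n_cells,
        onset_jitter_sd_s=spec.onset_jitter_sd_s, seed=spec.seed,
    )
    return generate_population(model_spec)
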