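# Methods

## One-substrate model

Eleven species: free enzyme `A` (active APC/C^Cdc20, nM), free substrate
`S0..S4` and enzyme-bound substrate `AS0..AS4`, indexed by the number of
attached ubiquitins. Mass-action reactions:

```
A + S_i  -> AS_i        k_a · A · S_i      (i = 0..4, including i = 4)
AS_i     -> A + S_i     k_d · AS_i
AS_i     -> AS_{i+1}    k_c · AS_i         (i < 4)
S_4      -> (degraded)  e · S_4
AS_4     -> A           e · AS_4
```

plus an APC/C input: either linear production of `A` at `p_A` (nM/s) from
`A(0) = 0`, or a constant pool `A(0) = A_const` with no production. All
ubiquitin-transfer steps share one `k_c` (single-chain, unbranched); E1/E2
charging and activator binding are not modelled explicitly, and the
proteasome appears only through the first-order rate `e`.

Two modelling choices are worth flagging because the reaction scheme admits
alternatives. First, `S4` is allowed to re-bind the enzyme (`k_a·A·S4`):
the fully modified substrate is still a substrate, and with `e = 1000`/s
the choice is numerically invisible since `S4` lives for about a
millisecond. Second, degradation of `AS4` returns `A` to the free pool —
the ligase is a catalyst and is not consumed with its product. Both choices
preserve the two balance laws the tests enforce: total enzyme is conserved
in constant mode (`A + Σ AS_i`, plus `Σ AC_i` with two substrates), and the
total-substrate flux is exactly `−e·(S4 + AS4)`.

Deubiquitination, when enabled, removes one ubiquitin per event at rate
`k_dub` from a variant-dependent species set: `all` (every ubiquitinated
species), `free_only` (`S1..S4`), `bound_only` (`AS1..AS4`), or `mono_only`
(`S1` and `AS1`). With `k_dub = 0` every variant reduces bitwise to the
plain model.

### Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `k_a` | 0.01 | /(nM·s) | enzyme-substrate association |
| `k_d` | varied | /s | complex dissociation |
| `k_c` | varied | /s | ubiquitin transfer |
| `e` | 1000 | /s | proteasomal destruction of 4-ubiquitin species |
| `p_A` | 0.06 | nM/s | linear APC/C^Cdc20 accumulation |
| `A_const` | 100 | nM | constant-mode APC/C^Cdc20 level |
| `S0_init` | 200 | nM | initial substrate (per substrate) |

These are the physiological anchors of the study system (yeast Clb5-scale
substrate abundance, Cdc20-scale enzyme accumulation); `e` is set high
enough that a fourth ubiquitin is equivalent to destruction — the tests
verify the 4-ubiquitin pool never exceeds 1 % of the initial substrate.

### Integration

The default integrator is LSODA (`rtol = 1e-8`, `atol = 1e-10` nM) on a
1-s output grid over 3000 s. The system is genuinely stiff: `e = 1000`/s
against grid rate constants down to `1e-3`/s spans nine decades of time
scales. A fixed-step explicit-Euler mode is kept as an independent,
transparent oracle; explicit Euler is only stable for `dt < 2/e`, so the
oracle runs at `dt = 1 ms` (tests compare total-substrate traces over a
300-s window, where the two routes agree to better than 0.5 %, typically
1e-4). A whole-second step would diverge, which is why the adaptive solver
— not step-for-step replication of a 3000-step integration — is the
reference path. Reported concentrations below 1e-9 nM are clipped to zero.

## Timing metrics

`T95` and `T50` are the first times total substrate (free + bound, all
ubiquitin counts) crosses 95 % and 50 % of its t = 0 value, located by
linear interpolation between 1-s output samples; `Td = T50 − T95`. The
baseline is the initial value, not a running maximum — without substrate
production the trace is non-increasing, so the first crossing is the only
crossing. A crossing that does not occur within the horizon is *censored*
and propagates as `None`/`NaN` into every derived ratio; censored cells are
excluded from region masks rather than filled with sentinels, because the
slow-degradation corner of the grid never reaches 50 % in 3000 s.

Peak occupancy is `max_t Σ_i AS_i / (A + Σ bound)`, skipping time points
with zero total enzyme (the first instant in linear mode).

## Parameter scans and sensitivity

The default grid is 25 log-spaced values of `k_c` and `k_d` on
[1e-3, 1e3] /s — neighbor ratio exactly `10^0.25 ≈ 1.778`, the "factor of
1.8" — and six values of `k_a` on [1e-4, 10] /(nM·s) with neighbor ratio
10. Region masks use `T95 > 200 s` (delayed onset) and `Td < 600 s` (fast
degradation); their conjunction is the overlap zone. Sensitivities
`(T95_base − T95_perturbed)/T95_base` re-simulate the perturbed set with
the exact factor `10^0.25` rather than reading a neighbor cell, so they are
valid off-grid; the two conventions agree up to the rounding of 1.8. Scans
trap per-cell solver failures (flagged, never aborting) and are
deterministic, so repeated runs write byte-identical CSVs.

## Two-substrate competition

Substrate C duplicates the S reaction set (species `C0..C4`, `AC0..AC4`)
with its own `k_d`, `k_c`; both substrates start at 200 nM and bind the
single free-`A` pool with the shared `k_a`. Scenarios make C the better
substrate either by affinity (`k_d_C = k_d_S/10`) or catalysis
(`k_c_C = 10·k_c_S`). Reported metrics and their denominators (which the
comparison "relative difference" leaves open; ours are stated explicitly):

- relative onset difference `(T95_S − T95_C)/T95_C`;
- `Td_C/Td_S` (C degrades faster when < 1);
- competition effect `(T95_S^two − T95_S^alone)/T95_S^alone`, with the
  one-substrate run of S at identical parameters as baseline.

Competition acts purely through enzyme sequestration, so the competition
effect is non-negative everywhere; the tests assert this with a 1e-6
slack for solver/interpolation round-off.

## Processivity

A stripped-down model starts with all material as `AS0` and no re-binding:
each complex races catalysis (`k_c`) against dissociation (`k_d`), and the
terminal ubiquitin-count distribution of dissociated substrate is the
per-binding-event processivity. Because each race is won independently
with probability `p = k_c/(k_c + k_d)`, the mean capped at four is
`p + p² + p³ + p⁴` — the closed form used as the oracle for the ODE route
(agreement within 1e-4 across the full grid). The ODE is integrated until
the bound pool falls below 1e-6 of its initial amount. `AS4` dissociates
at `k_d` like every other complex; since it can gain no further ubiquitin,
this affects only the waiting time, not the terminal counts. `k_d = 0` is
degenerate (nothing ever dissociates): the result is returned as average 4
with an explicit `never_dissociates` flag. Processivity depends only on
`k_c/k_d` — invariant under joint rescaling — unlike T95/Td, which also
feel `k_a`, concentrations and the APC/C input.

## Trace onset detection

Input traces are uniformly sampled intensity series (30-s default). The
detector smooths with a centered moving average (shrinking at the edges),
normalizes by the smoothed maximum (making detection invariant to overall
intensity scale), takes the central-difference first derivative, finds the
derivative minimum `m` (which must be negative, otherwise `no_decline`),
and scans backwards for the latest earlier sample with derivative
`≥ zero_fraction·m`; if none qualifies the call is the first sample,
flagged `no_plateau`.

The smoothing window and threshold are free parameters of the procedure,
and we calibrated them on noiseless synthetic ground truth covering both
decline shapes the generator produces. At 30-s sampling the
central-difference derivative already averages over a two-sample span; any
additional moving average of width `w` pushes the detected point a further
`(w−1)/2` samples before a sharp plateau-to-decline break, while a large
threshold pushes the call deep into a gradual (model-shaped) decline.
`window = 1` with `zero_fraction = 0.15` keeps both systematic errors
within one sample; these are the defaults, with wider windows available
for noisier data than the tests exercise. Residual accuracy: one sample
(30 s) early on sharp breaks, and within the 99 %-to-95 % decline window
on model-shaped traces.

Population comparisons use the two-sample t-test (Welch by default, pooled
selectable) on detected onset times.

## Synthetic traces

The generator emulates single-cell GFP degradation data: a flat plateau, a
decline that is either exponential (default rate 0.005 /s, i.e. a ~2.3-min
half-life, matching the several-minute degradation episodes the model
produces inside the overlap zone) or the resampled total-substrate curve
of a model run scaled to the plateau; additive i.i.d. Gaussian noise as a
fraction of the plateau; 30-s sampling over 1 h; optional per-cell Gaussian
jitter of the onset time. Every trace derives from `(seed, cell_index)`
alone — no hidden entropy. Deliberately absent: photobleaching, background
drift, cell-cycle alignment and segmentation artefacts; detector results on
these traces therefore demonstrate noise robustness, not robustness to
illumination or tracking errors in real microscopy data.

## Problem sizes used in the test suite

Full 25×25 grids are used wherever a claim is grid-wide (one-substrate
scans, both two-substrate scenario scans, the processivity map). The
fixed-step-oracle comparisons use a 300-s window (the onset-and-decline
part of the dynamics, which is where the solvers could disagree) because
the millisecond-step Euler reference costs ~10⁵ RHS evaluations per
simulated second. Conservation checks use 20 random rate-constant sets on
a 600-s window; onset-recovery statistics use ~200 traces across noise
levels.

## Known limitations

- Single unbranched ubiquitin chain, one shared `k_c` for every transfer
  step, no E1/E2/activator sub-steps, no proteasome kinetics beyond `e`.
- APC/C input is linear or constant; real activation dynamics are more
  complex.
- The two-substrate model stops at N = 2; no checkpoint (SAC) species.
- The explicit-Euler oracle is first-order: its `dt = 1 ms` accuracy floor
  (~1e-4 relative) is far above the adaptive solver's tolerance, so
  agreement bounds are set by the oracle, not the solver.
- Exact off-grid `(k_c, k_d)` scale invariance of the closed-form
  processivity holds bitwise only for power-of-two rescalings; general
  rescalings agree to floating-point rounding.
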