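# apckinetics

Kinetic modelling of ordered substrate degradation by the anaphase-promoting
complex (APC/C) bound to its activator Cdc20, plus onset detection for
single-cell fluorescence degradation traces.

During mitosis, substrates of APC/C^Cdc20 — an E3 ubiquitin ligase — are
degraded in a strict order (in budding yeast, the S-phase cyclin Clb5 before
securin) even though they share the same enzyme pool. This package is for
quantitative cell biologists who want to explore how that ordering can arise
from the kinetics of multi-step ubiquitination alone: how binding affinity,
catalytic rate, enzyme availability and substrate competition shape *when*
degradation starts and *how fast* it proceeds.

## The model

Free APC/C^Cdc20 (`A`) binds free substrate carrying *i* = 0..4 ubiquitins
(`S_i`) with association rate constant `k_a` (per nM·s); the bound complex
`AS_i` either dissociates (`k_d`, /s) or gains one ubiquitin (`k_c`, /s).
A substrate carrying four ubiquitins is destroyed by the proteasome
(`e` = 1000 /s, i.e. effectively instantly), releasing the enzyme if bound.
Active APC/C^Cdc20 either accumulates linearly at `p_A` = 0.06 nM/s from
zero, or is held constant. All reactions are mass action; there is no
substrate production. Substrate starts at 200 nM.

Two summary statistics capture degradation timing:

- **T95** — time for total substrate to fall to 95 % of its initial amount
  (the delay of degradation onset after APC/C^Cdc20 activation);
- **Td = T50 − T95** — time to go from 95 % to 50 % remaining (inverse
  measure of degradation rate).

A delayed onset (large T95) and a fast degradation rate (small Td) pull the
rate constants in opposite directions, so only a narrow diagonal band of
(`k_c`, `k_d`) space satisfies both — the package's scans map that band,
its sensitivity to ×1.8 changes in `k_c`/`k_d`, deubiquitination variants,
two-substrate competition for the shared APC/C pool, and the per-binding-
event processivity `p + p² + p³ + p⁴` with `p = k_c/(k_c+k_d)`.

## Worked example

```python
import apckinetics as ak

# an overlap-zone parameter set: delayed onset AND fast degradation
p = ak.RateParameters(k_a=0.01, k_c=0.0316, k_d=0.1)
m = ak.compute_timing_metrics(ak.simulate(p))
print(f"T95 = {m.T95:.1f} s, Td = {m.Td:.1f} s, "
      f"peak APC/C occupancy = {m.max_occupancy:.3f}")

# add a second substrate C that is ubiquitinated 10x faster
two = ak.TwoSubstrateParameters.catalytic(k_c_S=0.0316, k_d_S=0.1)
_, cm = ak.run_competition(two)
print(f"Td_C/Td_S = {cm.td_ratio:.3f}, "
      f"competition effect on S = {cm.competition_effect:.4f}")
```

prints

```
T95 = 476.6 s, Td = 350.8 s, peak APC/C occupancy = 0.947
Td_C/Td_S = 0.839, competition effect on S = 0.1495
```

So at this point the substrate sits untouched for ~8 minutes after
APC/C^Cdc20 starts accumulating, then drops from 95 % to 50 % in under
6 minutes while occupying essentially the whole enzyme pool. The
catalytically better competitor C degrades faster than S (ratio < 1) but
barely delays it (a 15 % increase of T95): fast catalysis keeps the C-bound
APC/C pool small, so C does not sequester the enzyme.

The same operations are exposed on the command line:

```sh
apckinetics simulate --config params.yaml --out out/   # time course + metrics
apckinetics scan --k-a 0.01 --out out/                 # 25x25 T95/Td maps
apckinetics compete --scenario catalytic --grid --out out/
apckinetics processivity --out out/
apckinetics synth --n-cells 30 --seed 1 --out out/     # synthetic GFP traces
apckinetics onset --traces out/traces.csv --out out/   # onset calls per cell
```

Config files are flat YAML/JSON mappings of `RateParameters` fields, e.g.
`{k_a: 0.01, k_c: 0.0316, k_d: 0.1, apc_mode: linear}`; units are nM and
seconds throughout. All CSV outputs are tidy (long-form) with a provenance
comment header.

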