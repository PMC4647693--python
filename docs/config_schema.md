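# Configuration file schema

Configs are flat YAML or JSON mappings. Unknown keys are rejected with an
error naming the key. All concentrations are in nM, all times in seconds.

## One-substrate model (`RateParameters`)

| key | type | default | units | notes |
|---|---|---|---|---|
| `k_a` | float >= 0 | 0.01 | /(nM·s) | association rate constant |
| `k_d` | float >= 0 | 1.0 | /s | dissociation rate constant |
| `k_c` | float >= 0 | 1.0 | /s | ubiquitin-transfer rate constant |
| `e` | float >= 0 | 1000.0 | /s | degradation of 4-ubiquitin species |
| `p_A` | float >= 0 | 0.06 | nM/s | APC/C accumulation (linear mode) |
| `A_const` | float >= 0 | 100.0 | nM | APC/C level (constant mode only) |
| `S0_init` | float >= 0 | 200.0 | nM | initial free unmodified substrate |
| `apc_mode` | `linear` \| `constant` | `linear` | | APC/C input mode |
| `deub_variant` | `none` \| `all` \| `free_only` \| `bound_only` \| `mono_only` | `none` | | deubiquitination target set |
| `k_dub` | float >= 0 | 0.0 | /s | deubiquitination rate constant |

Example:

```yaml
k_a: 0.01
k_c: 0.0316
k_d: 0.1
apc_mode: linear
```

## Two-substrate model (`TwoSubstrateParameters`)

Detected by the presence of `k_d_S` or `scenario`. Shared keys `k_a`, `e`,
`p_A`, `A_const`, `apc_mode` as above; per-substrate keys `k_d_S`, `k_c_S`,
`k_d_C`, `k_c_C` (/s) and `S_init`, `C_init` (nM, both default 200).
`scenario` is `affinity` (k_d_C = k_d_S/10), `catalytic`
(k_c_C = 10·k_c_S) or `custom` (rates given explicitly).
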