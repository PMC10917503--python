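# phytoclock

Compact plant circadian clock ODE models with split PRR9/PRR7 variants,
in-silico gene knockouts, light–dark entrainment / free-run simulation, and
rhythmicity analysis.

The base oscillator lumps eight clock genes into four mRNA/protein pairs —
CL (CCA1/LHY), P97 (PRR9/PRR7), P51 (TOC1/PRR5), EL (ELF4/LUX) — plus a
dark-accumulated, light-degraded factor P that mediates acute induction at
dawn (9 ODEs). Three 11-ODE variants split the merged P97 component into
separate P9 and P7 gene copies:

| Variant | Change relative to the base model |
|---------|-----------------------------------|
| MODEL1  | split only; each copy keeps the merged component's wiring |
| MODEL2  | CL additionally represses P9 (Hill half-max `K11 = (K4+K5)/2`) |
| MODEL3  | CL represses both P9 and P7, plus CL negative autoregulation |

Null mutants are simulated by zeroing transcription constants: `el` (the
evening-complex proxy for *elf3*) zeroes `v4`; `prr9`/`prr7` zero the
corresponding copy's `v2A` (and by default `v2L`). The standard protocol is
8 days of 12:12 light–dark entrainment followed by release into constant
light; free-run traces are classified RHYTHMIC / ARRHYTHMIC /
INDETERMINATE by an explicit threshold rule (peak count, amplitude
persistence, inter-peak regularity, period band — all config-exposed).

Parameter tables ship in `src/phytoclock/params/` (one flat YAML per
variant). The split-gene coupling convention is selectable: `sum_halved`
(default; downstream targets read `[P9]p + [P7]p` with halved production
rates, so the wild-type split model reproduces the base model exactly) or
`independent_full`.

## Python API

```python
import phytoclock as pc

params = pc.parameters_for_variant("MODEL2")
traj = pc.run_simulation("MODEL2", params,
                         genotype=pc.parse_genotype("elf3/prr9/prr7"))
fr = traj.free_run()
report = pc.classify_rhythmicity(fr.time_h, fr.component("CL_m"),
                                 ct_offset_h=traj.release_time_h)
print(report.call, report.period_h)
```

`genotype_matrix(...)` runs the full genotype × variant × component scan and
returns a tidy DataFrame of calls and metrics. `synthetic_data` generates
luminescence-style traces (known period/phase/damping/drift/noise, seeded)
for estimator validation, and `cli_io.ModelPlugin` is the seam for external
clock models (a non-faithful demo stub exposing the U2019.3 knockout
constant names `n3, n4, n7, n8, n9` ships for interface testing).

## CLI

```bash
phytoclock simulate -c config.yaml              # trajectory CSV + manifest
phytoclock scan-genotypes --variants MODEL1,MODEL2   # rhythmicity matrix
phytoclock analyze trace.csv --out report.json  # metrics for a trace CSV
phytoclock synth --out trace.csv --period 25 --noise-sd 0.1 --seed 7
```

Configs are flat YAML (variant, genotype, protocol, solver, thresholds,
seed); every run writes a manifest (config echo + version + output hashes)
sufficient to reproduce it. Trajectories are long-format CSV
(`time_h, zt_or_ct, phase_frame, component, value`) with a JSON sidecar.

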