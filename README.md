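# vfpop — population-based sensitivity analysis of a two-mass vocal fold model

`vfpop` simulates the symmetric Steinecke–Herzel (S&H) lumped-element model
of vocal fold vibration and asks a population-level question of it: across a
*virtual population* of phonating subjects — not just one nominal
configuration — how strongly and how consistently does each of the model's
16 inputs (subglottal pressure `P`, masses `m1`, `m2`, stiffnesses `k1`,
`k2`, `kc`, dampers `r1`, `r2`, geometry `d1`, `d2`, `L`, collision springs
`c1`, `c2`, rest areas `a01`, `a02`, and the smoothed-step scale `x0`)
influence each voice-source output (F0, mean/max flow, MFDR, open quotient,
speed quotient)?

It is aimed at voice-science and biomechanics researchers who need feasible
parameter ranges for reduced-order phonation models, or who want to know
which input–output effects generalize across a population rather than
holding only at a single operating point.

## Method in brief

1. **Virtual subjects.** Each of the 16 inputs is scaled independently by a
   factor `r^a`, `r ~ U(1, Rmax)`, `a = ±1` equiprobable, around the
   nominal vector; the model (two coupled mass-spring-damper oscillators per
   fold, Bernoulli aerodynamic loading, smoothed-step collision and flow
   switching) is integrated with fixed-step RK4 (dt = 0.01 ms, 1.5 s,
   0.5 s transient discarded) to produce the glottal flow `U(t)`.
2. **Normal-phonation filter.** Subjects are kept only when all six
   clinically bounded measures are normal: F0 88–263 Hz, mean flow 50–420
   cm³/s, AC flow 40–800 cm³/s, MFDR 100–1150 L/s², HRF −19–2.1 dB, H1−H2
   −24–11 dB (rejection sampling; the acceptance rate itself is a result).
3. **Per-subject sensitivities.** For every accepted subject and every
   input `x`, a +1% perturbation gives the non-dimensional sensitivity
   `S* = (ΔF/F)/(Δx/x)` for each output `F` — a *distribution* of S\* per
   input–output pair and sampling range (`Rmax ∈ {1.1, 1.2, 1.5, 2, 5}`).
4. **Designed-experiment baselines.** One-at-a-time variation, Cotter's
   2n+2 screening design, and a 231-point D-optimal quadratic response
   surface are provided for comparison.
5. **Adaptive resampling.** Success histograms of accepted factors are
   fitted with sampleable densities and used as the proposal distribution,
   raising the yield of normal-phonation subjects several-fold at broad
   ranges.

## Worked example

```python
import numpy as np
from vfpop import (ParameterSet, simulate, extract_measures, classify_normal,
                   generate_population, population_sensitivity, summarize_pairs)

res = simulate(ParameterSet.nominal())
m = extract_measures(res.flow)
print(f"F0 = {m.f0:.1f} Hz, mean flow = {m.mean_flow:.0f} cm3/s, "
      f"MFDR = {m.mfdr:.0f} L/s2, OQ = {m.oq:.2f}")
print("normal phonation:", classify_normal(m)[0])

pop = generate_population(rmax=1.5, n_target=30, seed=5)
print(f"accepted {pop.accepted}/{pop.attempted} subjects")
tensor = population_sensitivity(pop)
summ = summarize_pairs([tensor])
row = summ[(summ.input == "L") & (summ.output == "mfdr")].iloc[0]
print(f"S*(L -> MFDR): median {row['median']:.2f} "
      f"[{row.p5:.2f}, {row.p95:.2f}]")
```

prints (seeds fixed):

```
F0 = 135.8 Hz, mean flow = 250 cm3/s, MFDR = 362 L/s2, OQ = 0.65
normal phonation: True
accepted 30/133 subjects
S*(L -> MFDR): median 1.93 [1.74, 2.48]
```

i.e. the nominal model phonates normally at 135.8 Hz; at `Rmax = 1.5` about
one in four sampled subjects passes the normal-phonation filter; and a 1%
increase in vocal fold length raises MFDR by about 1.9% for the median
subject.

A command-line interface mirrors the library
(`vfpop simulate`, `vfpop sample-population`, `vfpop mc-sensitivity`,
`vfpop doe --method {oat,cotter,rsm}`, `vfpop resample`, `vfpop summarize`,
`vfpop plot`, `vfpop run-all --config study.yaml`).

## Layout

- `src/vfpop/model.py` — S&H two-mass model and RK4 integration (numba).
- `src/vfpop/measures.py` — voice-source measures and the normal-phonation filter.
- `src/vfpop/population.py` — multiplicative factor sampling, rejection,
  success histograms, density fitting, adaptive resampling, convergence check.
- `src/vfpop/sensitivity.py` — per-subject S\*, aggregation, OAT, Cotter,
  D-optimal quadratic RSM.
- `src/vfpop/reporting.py` — MDSD and mean-vs-SD figures, success curves,
  YAML config, end-to-end pipeline.
- `docs/methods.md` — modelling and numerical choices in detail.
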