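# Methods

## The model

The voice source is the symmetric Steinecke–Herzel two-mass model. Each
vocal fold is two coupled mass–spring–damper oscillators: a large inferior
mass `m1` (thickness `d1`) and a small superior mass `m2`, coupled by the
spring `kc`. With left–right symmetry one fold is integrated and mirrored,
giving the 4-state system `(x1, v1, x2, v2)`. Glottal areas follow the
displacements as `a_i = a0i + 2 L x_i`; the minimum `a_min = min(a1, a2)`
is the flow-limiting area.

Forces on mass *i* (g-cm-ms units):

- restoring spring `−k_i x_i` and damper `−r_i v_i`;
- coupling `−kc (x_i − x_j)`;
- collision `−Θ(−a_i) c_i a_i / (2L)` — a smoothed one-sided spring that
  engages as the area closes through zero;
- on mass 1 only, the aerodynamic (Bernoulli) load
  `L d1 P [1 − Θ(a_min)(a_min/a1)²] Θ(a1)`.

`Θ(y) = tanh(50 y / x0)` for `y > 0` and `0` otherwise is the smoothed step
with reference scale `x0`; it makes the vector field continuous across
glottal closure. The glottal volume velocity is the Bernoulli flow
`U = sqrt(2P/ρ) a_min Θ(a_min)` with fixed air density
`ρ = 0.00113 g/cm³` (a physical constant, not one of the 16 inputs).

Two bookkeeping consequences worth knowing: `d2` appears in no force or
flow term, so every sensitivity to `d2` is exactly zero (its presence keeps
the published 16-parameter interface); and `x0` enters only through `Θ`, so
its sensitivities are near zero but not degenerate.

## Integration

Classical fixed-step RK4 with `dt = 0.01 ms` over `1500 ms`; the first
`500 ms` are discarded as transient. Initial conditions
`x1 = x2 = 0.01 cm`, `v1 = v2 = 0`; since only the steady state is
analysed, they affect nothing but the discarded span. Halving `dt` moves
the nominal F0 by well under 0.5% (tested), which is the adequacy criterion
for the step size. Divergence (state magnitude beyond 1e6) marks the
subject failed rather than raising, so population runs continue.

The population fast path stops integrating early when the fold motion has
demonstrably decayed during the transient (peak-to-peak `x1` excursion
below 1e-4 cm *and* shrinking at least 4-fold between consecutive 125-ms
windows). Such a trajectory is in the linear contraction regime and cannot
return to sustained oscillation; the subject is classified non-oscillating
either way, and the shortcut roughly halves the cost of rejection sampling
at broad ranges. The full-trajectory API never takes this shortcut.

## Voice-source measures

Cycles are delimited by upward crossings of `0.01 × max U` (the 1%
threshold also defines the "open" phase for OQ and SQ; it is robust to
floating-point leakage near closure). At least 20 complete cycles are
required for a valid analysis. Per cycle period CoV is reported as a
steadiness diagnostic but does not reject subjects: the filter is the set
of clinical bounds alone, and the symmetric noise-free model produces
near-periodic waveforms whenever it oscillates at all.

- `F0` — reciprocal mean cycle period, Hz.
- `mean/max flow` — time average / maximum of `U` over whole cycles, cm³/s.
- `AC flow` — mean per-cycle peak-to-trough amplitude, cm³/s.
- `MFDR` — maximum of `−dU/dt`, centered differences at the integration
  step, no smoothing (the waveform is smooth; smoothing would bias the
  peak), L/s².
- `OQ` — mean fraction of the cycle with `U` above threshold.
- `SQ` — mean ratio of rise to fall duration within the open phase.
- Harmonic measures are read from the Fourier series of the
  period-averaged cycle (up to 64 cycles resampled to a 1024-point phase
  grid and averaged — identical to an integer-cycle rectangular-window DFT
  for a periodic signal, and much cheaper). `HRF` is the harmonic power
  above the first relative to the first on the **flow** spectrum, the
  convention of the clinical HRF literature. `H1−H2` is the level
  difference of the first two harmonics of the **radiated** source — the
  flow derivative, i.e. harmonic `n` weighted by `n` (+6 dB/octave) — the
  convention under which the published normal ranges were measured. With
  flow-spectrum H1−H2 the nominal model would sit just outside the normal
  band (11.46 dB vs the 11 dB bound), contradicting the requirement that
  the nominal configuration and its ±7% neighbourhood phonate normally;
  the radiated convention puts it at 5.44 dB with a comfortable margin.
  Harmonics below −80 dB re H1 are treated as numerical noise; fully
  degenerate spectra are floored/ceilinged at ±100 dB and flagged.

Normal phonation = oscillating **and** all six bounds met inclusively:
F0 88–263 Hz, mean flow 50–420 cm³/s, AC flow 40–800 cm³/s, MFDR 100–1150
L/s², HRF −19–2.1 dB, H1−H2 −24–11 dB.

## Population sampling

Factors `r^a` with `r ~ U(1, Rmax)`, `a = ±1` equiprobable, independent per
parameter, give a multiplicative spread over `[1/Rmax, Rmax]` with equal
mass above and below nominal. The study grid is
`Rmax ∈ {1.10, 1.20, 1.50, 2.00, 5.00}`. Rejection sampling continues
until the target number of accepted subjects (default cap: 200 × target
attempts). Each attempt draws from its own RNG substream keyed by
`(seed, attempt index)`, so results are reproducible and independent of
evaluation order.

Success histograms use 25 equal-width bins on the log-factor axis. The
fitted density is a monotone piecewise-linear CDF through the
moving-average-smoothed (width 3) bin masses — shape-agnostic and exactly
invertible for inverse-CDF sampling. Adaptive resampling draws every one of
the 16 factors from its fitted density (re-sampling only the skewed
parameters was the alternative; all 16 keeps the procedure uniform and the
structureless densities are harmless by construction).

## Sensitivities

`S* = ((F_pert − F_base)/F_base)/δ` with a **+1% forward difference**
(δ = 0.01, configurable). Records are invalid when the perturbed run fails
to oscillate or the base output is zero; summaries exclude them and report
counts. Per range, medians and 5th/95th percentiles are computed over
subjects, then averaged arithmetically across the five ranges. Inputs are
ranked by the mean over outputs of the absolute averaged median, ties
lexicographic. Pair consistency at one range: `consistent` if
`|mean| ≥ 2·sd`, `within-1sd` if `|mean| < sd`, else `within-2sd`; the
degenerate zero-effect pair (`mean = sd = 0`, i.e. `d2`) lies at the apex
of the shaded wedge and is classed inside the shading — it has no
consistent significant effect.

The six outputs tracked per subject are F0, mean flow, max flow, MFDR, OQ
and SQ. HRF and H1−H2 serve in the normal-phonation filter but are not
sensitivity outputs.

### Designed-experiment methods

- **OAT**: 16 × 2 runs at nominal ± the half-range; the pair sensitivity is
  the normalized central difference. A failed endpoint invalidates the pair
  — the method's documented failure mode at broad ranges.
- **Cotter**: the 2n+2 = 34-run design (all-low, one-high-each, one-low-each,
  all-high) with odd/even indices
  `C_odd = ¼[(y_allhigh − y_onelow) + (y_onehigh − y_alllow)]`,
  `C_even = ¼[(y_allhigh − y_onelow) − (y_onehigh − y_alllow)]`; a single
  failed run invalidates the whole analysis.
- **RSM**: a 231-point D-optimal subset (greedy determinant-gain
  construction plus Fedorov exchange passes) of ~4100 candidates (scrambled
  Sobol points plus centre and axis points) on the normalized hypercube,
  fit by least squares to the full 153-term quadratic; sensitivities come
  from the analytic gradient at the nominal point. Design coordinates map
  linearly onto the factor interval `[1/Rmax, Rmax]` (`f = c + s·z`), which
  makes polynomial responses in the factors exactly polynomial in `z`; the
  nominal point sits at `z = (1 − c)/s`, slightly off-centre. Validation
  simulates fresh uniform points and reports the mean over points of the
  max over outputs of the relative error ("average maximum error"), plus
  per-output means so other parses of that phrase are checkable.

## What the synthetic populations do and do not emulate

The generator reproduces the study's sampling law and rejection filter
exactly, so passing tests demonstrate the pipeline's statistical behaviour
under the model's own dynamics. It does not emulate physiological
correlations between parameters (muscle-activation rules linking `L`, `d1`,
`k1`, `m1`), left-right asymmetry, vocal-tract loading, turbulence or
jitter — all deliberately absent; sensitivities are therefore *independent*
parameter effects, which is what makes them interpretable but also why,
e.g., the F0-vs-pressure slope (~1.3 Hz per cm H2O at the nominal point,
approaching 1 over large excursions) undershoots human data (3–5 Hz per
cm H2O).

## Scale choices

Reference results use 1000 subjects per range (a convergence check —
median stability of the top pairs across population sizes — motivates that
number). The bundled acceptance script reproduces the headline numbers
with 200–300 subjects per range and ~500 accepted subjects at `Rmax = 5`,
with bootstrap confidence intervals as tolerances; those sizes keep a
single-CPU replication in the tens of minutes while leaving the binomial
and bootstrap bands a few times wider than at full scale.

## Known limitations

- The operational definitions of the clinical measures (threshold choice,
  radiated-spectrum H1−H2) are reconstructions of standard practice; other
  reasonable conventions shift the filter boundary slightly and hence the
  absolute success rates (the 11 dB H1−H2 bound passes within ~1 dB of the
  nominal configuration under any convention).
- OQ and SQ are computed from the flow waveform, not the area waveform;
  flow-based OQ is systematically a little smaller near closure.
- D-optimality is a local-search optimum, not a certificate; the design is
  only guaranteed to beat random subsets (tested), which is all the fit
  requires.
- At `Rmax = 5` a 500-subject histogram base leaves visible bin noise in
  the fitted densities; the adaptive success rate is correspondingly a
  conservative estimate of what a 1000-subject base would achieve.
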