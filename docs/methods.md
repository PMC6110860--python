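# Methods

## Membrane tension from suction

Tension in a patch-clamped membrane dome follows Laplace's law,
`T = P·R_d/2`, with `P` the magnitude of the transmembrane pressure and
`R_d` the radius of curvature of the patch. Conversion is fixed at
1 mmHg = 133.322 Pa; with `P` in mmHg and `R_d` in μm the result is in
mN/m. Suction is stored as *negative* pressure everywhere in protocols
and traces (the acquisition convention); the mechanics functions take
magnitudes, and the conversion happens explicitly at the call boundary.

## Aspirated area of a conical pipette

For a membrane pulled a length `L` into a conical pipette of tip radius
`r` and dome radius `R`, capped by a spherical dome of height `h`, the
aspirated surface area is the frustum lateral surface plus the cap:

    A = π(r + R)·√((R − r)² + L²) + 2πRh

A widely circulated typeset form of this expression,
`π(r+R) + √((R−r)²+L²) + 2πRh`, is dimensionally inconsistent (it adds
lengths to an area); the product form above is the geometrically
coherent reading and is what this package implements. Degenerate cases
follow from the formula: `r = R, h = 0` gives a cylinder (`2πrL`), and
`L = 0, r = R` leaves only the cap (`2πRh`).

Areal strain is `α = (A − A₀)/A₀` with `A₀` the zero-pressure reference
area. When a series lacks an explicit zero-pressure frame the
lowest-pressure frame is used and a warning is logged.

## Areal elasticity modulus

In the quasi-linear regime the tension–strain relation is
`T = K_A·α (+ T₀)`. Two least-squares estimators are exposed:

- `method="ols"` — regress tension on strain; `K_A` is the literal
  slope of the `T` vs `α` plot. This is the default for
  `fit_elasticity` and for the MD pipeline.
- `method="inverse"` — regress strain on tension and report
  `K_A = 1/slope`. This is the default inside `ma_pipeline`: in
  aspiration the suction steps (hence tensions) are controlled
  essentially exactly, while the measurement noise lives in the
  geometry-derived strain. Regressing the noisy variable on the exact
  one is the statistically consistent calibration; the reverse OLS
  suffers errors-in-variables attenuation that biases `K_A` low by
  `var(α)/(var(α)+σ_α²)`, which is material for stiff membranes whose
  strain range is small relative to the strain noise.

Both variants admit a free intercept (default) or a through-origin
constraint; the intercept is reported so users can check it is near
zero, as the noiseless law implies. Whether the original experimental
fits were constrained through the origin is not documented, hence both
are available. The fitted standard error of the slope, `r²` and the
point count accompany every estimate. Fewer than two distinct abscissa
values raises a degenerate-fit error.

## Trace idealization

The idealizer is a half-amplitude threshold detector:

- **Baseline** — median of the zero-pressure prefix of the sweep
  (samples whose |pressure| is below 2% of the peak, at the start);
  baseline noise is estimated by MAD. At least 10 prefix samples are
  required.
- **Unitary amplitude** — if not hinted, the separation between the two
  dominant modes of the all-points current histogram (256 bins, lightly
  smoothed; candidate open modes must be ≥ 4 noise SD away from the
  baseline mode and carry ≥ 2% of its mass). The estimate is then
  refined as the mean of level-1 samples minus baseline, excluding
  samples adjacent to level changes so that filter smearing does not
  bias the level means.
- **Level assignment** — a hysteresis quantizer: the level switches to
  `round((x − baseline)/amp)` only when the signal departs from the
  current level by more than 0.5 + 0.15 amplitudes (deadband 0.15).
  Events shorter than 2 samples are merged into the surrounding level.
- **Sub-conductance states** — collapsed onto the nearest integer level
  for NPo and thresholds; the fraction of open-level samples sitting in
  the 0.25–0.75 amplitude band below their level is reported separately
  as substate occupancy. With a 0.5-amplitude substate the blind mode
  separation is ambiguous by construction, so traces from substate-rich
  channels should be idealized with the full amplitude as a hint.

Gating statistics derived from the idealization:

- **Unitary conductance** `= |amplitude|/|V|` (nS from pA/mV).
- **NPo** — time-weighted mean level index over a window.
- **First-opening pressure** — pressure at the sample of the first
  all-closed → open transition (onset sample, no debounce window; where
  the threshold was read within the original analysis is not
  documented, and the onset is the reproducible choice).
- **Hysteresis** — on a symmetric loading/unloading ramp, the opening
  pressure from the loading phase and the closing pressure at the *last*
  open → all-closed transition of the unloading phase. With several
  open channels the return to the all-closed level is the unambiguous
  closing marker; this convention is a documented choice. The ratio
  |closing|/|opening| is 0, with a `stuck_open` flag, when the patch
  still conducts after the suction is fully released.
- **Amplitude classes** — in multi-species patches, opening steps are
  assigned to the nearest configured unitary amplitude (ties to the
  smaller), giving per-species first-opening pressures from one sweep.
- **Rectification** — independent least-squares slopes through the
  positive- and negative-voltage I–V points (≥ 2 each side), reported
  in pS with the reduction `1 − G_neg/G_pos`.
- **SEM** — sample standard deviation / √n throughout.

## Slab-averaged bilayer areas

Stretched-bilayer frame data enter as M×N matrices (trajectories ×
slabs) of cross-sectional areas between the phosphate planes. The area
observable is the grand mean `A = ΣΣ A_i/(M·N)`; an
`equilibration_exclusion` count drops leading trajectories that are not
yet steady (default 0 — how many repeats to discard is a data-quality
judgement, and inspecting area stationarity before excluding is
recommended). Strains against the zero-tension reference feed the same
free-intercept tension-on-strain fit as the experimental pipeline, for
comparability; at the ~1% area noise typical of these matrices the
errors-in-variables attenuation is negligible (< 0.2%), so plain OLS is
appropriate there. Per-slab volume weighting is not applied (the
averaging convention beyond the plain mean is not documented).

## Synthetic channel model

Each channel is a two-state continuous-time Markov chain with rates

    k_open  = k₀ · exp(β (T − T_half))
    k_close = k₀ · exp(−β (T − T_half)) · exp(−γ · max(Vp, 0))

with `T` the instantaneous Laplace tension of the protocol, `T_half` the
half-activation tension, `β` the tension sensitivity, `k₀` the rate
scale and `γ` the voltage coupling. This is phenomenological, not
mechanistic: the symmetric exponential is the minimal scheme with the
right stationary occupancy `k_o/(k_o+k_c)` and tension threshold, and
the `γ` factor delays closing at positive pipette voltages, reproducing
voltage-dependent hysteresis up to a stuck-open regime.

The chain is propagated with the exact two-state transition
probabilities over each sample interval (rates frozen per interval), so
state changes land on sample boundaries and the returned event log is
exact at the recording resolution — on noiseless, unfiltered traces the
idealizer reproduces it transition for transition. Rate exponents are
clipped at ±60 and rates capped at 10⁶/s; above the cap the per-sample
state is effectively a stationary draw, the correct fast-flicker limit
at the 5 kHz default sampling. The acquisition chain is emulated by a
single-pole low-pass at 2 kHz (configurable off) applied to the clean
current, with Gaussian noise (default SD 0.5 pA) added afterwards so the
configured value is the noise observed at the recorded bandwidth.

Presets (defaults chosen once, from the published channel parameters):

| preset      | G₊ (nS) | G₋ (nS) | T_half (mN/m) | β (per mN/m) | k₀ (1/s) | γ (per mV) |
|-------------|---------|---------|---------------|--------------|----------|------------|
| mscCG       | 0.34    | 0.113   | 5.5           | 10           | 5        | 0.65       |
| mscCG2      | 1.0     | 1.0     | 12            | 10           | 5        | 0 (substate 0.5) |
| cgmscl      | 3.7     | 3.7     | 12            | 10           | 5        | 0          |
| mscCG-rect  | 0.286   | 0.095   | 5.5           | 10           | 5        | 0.65       |

`mscCG`'s negative-branch conductance is its positive conductance scaled
by the measured 95/286 slope ratio; `mscCG-rect` carries the measured
slope conductances verbatim for I–V work. `β = 10/(mN/m)` makes the
channels steeply tension-sensitive: on the slow ramps used here the
first-opening tension overshoots `T_half` by `ln(βc/k₀)/β ≲ 0.1 mN/m`
(`c` the tension ramp rate), so first openings concentrate at
`P ≈ 2·T_half/r` within a few percent. `γ` is qualitative only — no
kinetic rates are published — and was set so the hysteresis-ratio vs
voltage curve decreases monotonically and reaches stuck-open near
+100 mV.

The aspiration generator inverts the analysis exactly: per pressure
step it computes the Laplace tension, draws a target strain
`α = T/K_A + N(0, σ_α)`, and solves the protrusion length by Brent
bisection (bracket [0, 10⁴] μm, xtol 10⁻¹²) so the conical-pipette area
reproduces that strain against the zero-pressure reference row. The
default pipette (tip 2.0 μm, dome and curvature radius 2.5 μm, dome
height 0.5 μm, reference protrusion 1.0 μm) maps the −10…−40 mmHg step
protocol onto tensions of ~1.7–6.7 mN/m — strains up to ~0.45 for a
soft `K_A ≈ 15 mN/m` membrane, consistent with the published pressures
and moduli themselves. The slab-area generator draws each entry as
`A₀(1 + τ/K_A)·(1 + cv·N(0,1))`.

## What the synthetic data do and do not emulate

The generators reproduce the statistical structure the analyses consume:
tension-dependent stochastic gating with distinct unitary amplitudes,
voltage-coupled closing, rectifying open-channel currents, quasi-linear
tension–strain mechanics, and trajectory/slab-structured area noise.
They do not emulate seal instability, baseline drift, capacitive
transients, channel inactivation or desensitization (absent in MscCG),
correlated gating between channels, membrane lysis, or non-linear
(viscoelastic) membrane regimes. Passing tests therefore demonstrate
correctness of the estimators under the stated noise models, not
robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Simulated sweeps default to 5 kHz sampling; recovery studies use 8–20 s
triangle ramps (40k–100k samples), 20–50 seeds for averaged quantities
and 5 seeds for the threshold-ratio experiment, matching the replicate
counts of the corresponding published measurements where they exist.
Determinism: every generator consumes a `NoiseSpec.seed`; identical
seeds give bit-identical traces, geometry tables and area matrices.
Report floats are serialized at 6 significant digits with sorted keys,
so re-runs are byte-identical apart from the timestamp.

## Known limitations

- The kinetic scheme is two-state; sub-conductance occupancy is modelled
  as a nested symmetric flicker and reported but not fitted (no
  dwell-time distribution fitting, by design).
- The idealizer is a threshold detector, not an HMM; events shorter than
  two samples are unrecoverable by construction.
- `K_A` estimates assume the quasi-static linear regime; no
  time-dependent (viscoelastic) membrane response is modelled.
- Slab areas are consumed precomputed; trajectory formats (DCD/XTC) are
  not read.
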