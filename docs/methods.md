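# Methods

This note records the models implemented in `ncis`, their assumptions,
the numerical choices behind the fitting procedures, and what the
synthetic-data generator does and does not emulate.

## Parallel-RC cell model (`ncis.circuit`)

After baseline subtraction removes the constant wall capacitance, a
capacitively coupled conductivity cell is modelled as a solution
resistance `R = Kcell/κ` in parallel with a coupling capacitance `C1`:
`Z = R/(1 + iωRC1)`. The measured quantities are the changes
`ΔZ = Z(κ0) − Z(κb)` against a baseline solution of conductivity `κb`
(ultra-pure water, 5.5 µS/m, in the bottle configuration). The module
exposes both the complex form (`impedance_rc`) and the expanded real /
negative-imaginary closed forms (`delta_z_real`, `delta_z_neg_imag`);
their equality on well-conditioned inputs is a test invariant.

**Capacitance–geometry link.** The model assumes the same electrode
geometry couples the resistive and capacitive paths, which fixes
`C1 = εr ε0 / Kcell`. This is the only dimensionally consistent
relation producing a capacitance in farads, and it makes the RC corner
`τ_RC = εr ε0 / κ` geometry-independent — equivalently the real response
peaks at `κ0,d = ω εr ε0` with height `1/(2ωC1)`, independent of `Kcell`.
Note that a directly contacting reference cell can have a very different
cell constant from the one implied by a through-wall `C1` (the coupling
path sees a different effective geometry); `resistance()` therefore
reports `R` from whatever cell constant the caller supplies and the
module makes no attempt to reconcile the two.

Constants: `ε0 = 8.8541878128e-12 F/m`; `εr` defaults to 78 (water) and
is configurable everywhere.

**C1 calibration (`fit_circuit`).** Joint weighted least squares of both
channels over all (frequency, conductivity) records, one free parameter.
Residuals are scaled per channel by the channel's maximum absolute value
so the small imaginary values are not drowned by the real part; the
optimization runs in `log10 C1` with bounds `[1e-15, 1e-9] F`.
Initialization uses the closed-form peak height `C1 = 1/(2ω·max ReΔZ)`
at a frequency whose sampled conductivities straddle its own `κ0,d`,
falling back to 1 pF. Fewer than two distinct conductivities (or
identically zero changes) is an error, not a degenerate fit.

**Out of scope.** Constant-phase elements, Warburg or inductive branches
(a plain RC describes through-wall data well inside the sensitivity
band), the low-frequency/high-conductivity deviations seen in bottle
data, and any electrode field simulation.

## Growth models (`ncis.growth`)

Time is in **hours** throughout. The logistic sigmoid
`U(t) = Ua/(1 + e^{−(t−t0)/τ})` has a *signed* amplitude: channels that
decrease during growth (reflection, some high-frequency impedance
channels) are fit with `Ua < 0`, never via absolute-value preprocessing.

`fit_sigmoid` is a bounded nonlinear least-squares fit (lmfit).
Initialization: `Ua` from the signed end-to-end range, `t0` from the
half-range crossing, `τ = (t75 − t25)/2.2` from the quartile crossings,
with `τ ∈ [1e-3, 100] h`. Constant curves raise a degenerate-data error;
fewer than four points an insufficient-data error.

**Two-region model.** Growth is split into a wall film (outer shell,
constant resistivity index `ρa2`) and a bulk cylinder (index `ρ1(t)`
sigmoidal with lag `t0b`). The film thickens with the cube root of
exponential volume growth, shrinking the bulk radius as
`r1 = r2 e^{−(t−t0w)/(3τu)}` after the wall lag `t0w`. The two regions
conduct in parallel (`two_region_re_dz` implements the parallel-
conductance form and is tested against an independently computed
`1/(G1+G2)`). Reducing the chain gives the dimensionless signal
`unified_growth` with parameters `(Un, τu, t0w, t0b, ρa1/ρa2)`; `Un`
absorbs the geometric prefactor `h ρa1 / (π r2²)`. The reduced form is
what is fit; the full geometric chain is exposed separately so the
reduction can be verified numerically.

**Unified fit (`fit_unified`).** Mirrors the measurement workflow in two
stages: (i) individual sigmoid fits of the low- and high-frequency
channels; the wall lag is identified with the low-frequency channel's
fitted `t0`, the bulk lag and `τu` with the high-frequency channel's;
(ii) per channel, a 1-D least squares over `ρa1/ρa2` against the
min-max-normalized data, with an affine (scale + offset) profile solved
in closed form. The affine rather than scale-only profile is used
because min-max normalization shifts the curve by its sampled minimum;
with an offset the normalized truth is exactly representable and
noise-free fits recover parameters to machine precision.

By default a **joint refinement** follows: multistart bounded least
squares over `(τu, t0w, t0b, log ρ_low, log ρ_high)` on both normalized
channels, started from the stage-1 estimates plus 5 %/15 %/30 % rise
times of the low channel and three ratio guesses. The refinement exists
because the frozen-lag two-stage procedure is *biased on data that truly
follow the two-region model*: a two-region curve's sigmoid half-rise is
not at `t0w` (for the wall-dominant shape with ratio 3.5 the stage-1 lag
lands ~1 h late and the frozen-lag ratio estimate collapses to ~1.7).
The multistart guards against the local minimum next to those biased
starting lags. `refine=False` reproduces the frozen-lag literature
procedure verbatim for comparison. A `lag_order` warning is raised when
the stage-1 lags come out inverted (`t0w ≥ t0b`), as when the caller
swaps the channels; note that for genuinely two-region-shaped inputs the
stage-1 ordering itself can invert, so the flag is advisory.

Not modelled: Gompertz/Baranyi growth laws, a mortality-phase term, and
spatially resolved biofilm structure.

## Comparison pipeline (`ncis.pipeline`)

* **Baseline subtraction** at a chosen time (linear interpolation
  between samples; per frequency for spectrum series); idempotent.
* **Normalization** `uN = (u − umin)/(umax − umin)`; channels flagged as
  reflection-like are plotted/fit as `1 − uN`. Flags are channel
  metadata, never inferred from names at analysis time.
* **Delays** are differences of fitted sigmoid lags,
  `tdelay = t0(channel) − t0(OD)`, not threshold crossings of raw data.
  Because fits run on min-max-normalized curves, truncation of the
  sigmoid tails at the observation-window edges biases `t0` by up to
  ~0.015 h under the default windows — negligible against the 0.1 h
  precision at which delays are conventionally reported.
* **Slot averaging**: the dense impedance series is averaged in closed
  windows `[ti − tsample/2, ti + tsample/2]` around each OD sampling
  time (shifted by the channel's delay so growth phases align). A point
  on a boundary shared by two slots goes to the *earlier* slot; empty
  slots are reported with `n = 0`, not raised.
* **Regression** of slot means against OD is ordinary least squares
  restricted to the *closed* OD window `[0.16, 1.3]` (configurable);
  `R²` is the OLS coefficient of determination. Closed-interval
  membership and the earlier-slot tie-break are deterministic choices —
  the boundary conventions are not dictated by the measurement
  procedure itself.

No optical physics (OD/OR are numeric channels) and no temperature
correction of growth data (at the recorded millikelvin stabilities the
2 %/°C coefficient moves conductivity by ≲0.1 %).

## Synthetic data (`ncis.synth`)

The generator reproduces the *statistical structure* of the instrument
data, not its physics:

* **Sweeps**: forward-model values at all (f, κ) combinations with
  multiplicative, mean-one Gaussian noise per channel. Defaults mirror
  the reported relative standard deviations — 0.7 % (real) / 0.04 %
  (imaginary) for the bottle configuration, 0.7 % / 0.06 % for the well
  plate (3.6 % / 0.14 % applies to its lowest frequency, 5 MHz). Noise
  is relative to each point's model value — the natural choice when a
  sweep spans six decades of conductivity.
* **Growth experiments**: channels generated from sigmoid or two-region
  parameters; the OD channel is subsampled at `tsample` (default
  0.75 h, within the 0.5–1 h practice) with uniform timing jitter of
  ±10 % of the interval; channel noise defaults to 1 %. Channel
  amplitudes in the named scenarios (1e5 Ω at 15 kHz, 2e4 Ω at 300 kHz,
  OD plateau 2.0, OR drop 0.5) are representative scales chosen once;
  all comparisons are normalization-invariant, so only their signs
  matter to the results.
* **Temperature**: Gaussian jitter around the setpoint mapped to a
  conductivity factor `1 + c·(T − T̄)` with `c = 2 %/°C` by default.
  (The printed broth conductivities 1.49 → 1.75 S/m over 25 → 37 °C
  imply ≈1.45 %/°C; the conventional 2 %/°C is kept as the default and
  is configurable.)
* **Determinism**: every generator takes a seed; nonzero noise without
  a seed is refused; zero-noise output equals the forward model
  bit-for-bit.

Named scenarios (`kcl_sweep_bottle`, `kcl_sweep_wellplate`,
`s_epidermidis_bottle`, `e_coli_bottle`, `s_epidermidis_wellplate`) are
pre-loaded with the corresponding published parameter sets (lags and
time constants per species and channel, C1 per configuration).

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: instrument drift and 1/f noise,
flow-loop disturbance during OD sampling (the dominant source of slot
scatter in practice), the low-frequency bottle deviations from the RC
model, saturation of OD and reflection above the valid window, and any
mechanistic link between bacterial metabolism and conductivity.

## Problem sizes and tolerances

Monte-Carlo suites use 50 replicates; sweeps use 4 frequencies × 7
conductivities; growth grids use 100–700 points over 3–14 h windows.
These sizes keep the full test suite and the acceptance script in the
tens of seconds while leaving Monte-Carlo medians stable to well inside
the asserted tolerances (C1 bias < 1 %, RMSE < 2 %; median τ within
10 %; median ρa1/ρa2 within 15 %; lags within 0.2 h). Oracle-equality
checks (complex RC vs closed forms, parallel-conductance form, OLS vs
normal equations) are asserted at 1e-10–1e-12 relative on
well-conditioned inputs; the complex-difference route loses precision by
cancellation when both conductivities are far below `ω εr ε0`, so those
comparisons draw points inside the sensitivity band.
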