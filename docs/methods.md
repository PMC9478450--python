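# Methods

## Physical model

The forward model treats the sapwood as an infinite, homogeneous,
isotropic medium with thermal diffusivity `k` (cm² s⁻¹) through which the
heat field is advected at the heat-pulse velocity `v` (positive up-tree,
toward the downstream probe). The heater is an ideal line source
perpendicular to the flow; an instantaneous pulse produces the
conduction–convection solution

    ΔT(x, t) = q / (4 π k t) · exp(−(x − v t)² / (4 k t)),

where `x` is the signed axial offset from the heater and `q` (K cm²)
scales the deposited heat per unit heater length. A pulse of finite
duration `t0` is the uniform superposition of instantaneous sources over
the emission interval,

    ΔT(x, t) = (1/t0) ∫₀^min(t, t0) ΔT_inst(x, t − s) ds,

evaluated by adaptive quadrature (relative tolerance 1e-8; the test suite
keeps an independent fixed-step Riemann-sum oracle at Δs = 1e-3 s).

Two identities of this model make it a sharp correctness oracle:

* **Log-ratio identity.** `ln[ΔT(x,t)/ΔT(−x,t)] = x v / k`, independent of
  time — exactly the HRM estimand. It survives finite pulse durations
  unchanged when the spacings are equal, because the instantaneous kernels
  at `±x` differ by the constant factor `exp(x v / k)` at every age.
* **Peak-time identity.** The downstream maximum of the instantaneous
  solution satisfies `v² t_m² + 4 k t_m − x² = 0`, which the Tmax formula
  inverts exactly. For the top-hat pulse, the peak condition becomes
  `f(t_m) = f(t_m − t0)` with `f` the instantaneous kernel, and solving it
  for `v` gives the finite-pulse Tmax form
  `v = sqrt((4k/t0) ln(1 − t0/t_m) + x²/(t_m (t_m − t0)))` — also exact,
  and reducing to the instantaneous form as `t0 → 0`. Both reductions are
  pinned by tests, which resolves the typographic ambiguity in common
  printings of these formulas.

Note that the *axial* integral of the line-source field is **not**
conserved in time (it decays as `1/√t`); energy conservation holds for the
full two-dimensional field. The simulator test checks the correct form:
the finite-pulse axial integral equals the emission-time average of
instantaneous axial integrals.

## Measurement cycle and processing pipeline

A cycle is 5 s of baseline sampling, a ~2 s pulse, and 100 s of
monitoring, all at 0.5 s intervals (the common field program; all three
durations are configurable). Processing per cycle and radial depth:

1. **Baseline subtraction** — mean of the pre-pulse samples (≥ 3
   required); a baseline standard deviation above 0.05 K flags
   `unstable-baseline` without aborting.
2. **HRM window ratio** — `ln(ΔT_d/ΔT_u)` per sample, averaged over the
   60–100 s window. Samples where either rise is below the 0.001 K floor
   are excluded and counted; an empty window is a low-signal error.
3. **Peak finding** — 3-sample moving average, discrete argmax, parabolic
   refinement through the peak and its neighbours. A maximum on the final
   sample raises `unresolved-peak` (window too short for the velocity).
4. **Péclet number** — `β = ln(ΔT_d,max/ΔT_u,max)` from the same smoothed
   maxima as the peak finder, so HRM/Tmax selection is noise-robust.
5. **DMA selection** — HRM iff `β ≤ 1` (inclusive, fixed, deliberately not
   configurable); the generalised HRM form is evaluated at the window
   midpoint (80 s). If the selected method fails (e.g. Tmax radicand
   negative), the other is used and flagged `dma-fallback`. When the
   upstream peak is below the floor, β is treated as +∞ (Tmax branch),
   which is the physically correct limit for fast flow.
6. **Flux** — wound correction `V_c = B V_h`, heat-capacity conversion to
   SFD, and annulus-weighted summation to whole-tree flow.

Each depth is processed independently (its own β and method); a config
switch (`shared_method`) instead applies the mean β across depths to all
of them, for users who prefer one method per probe pair.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `k` | 2.5×10⁻³ | cm² s⁻¹ | common fresh-sapwood nominal; supply a measured value for quantitative work |
| `x_d`, `x_u` | 0.5 | cm | standard close-spacing installation |
| `t0` | 2.0 | s | typical pulse program |
| depths | 0.5, 1.5, 2.5 | cm | three-point radial profile |
| HRM window | 60–100 | s | the customary late-time averaging interval |
| ΔT floor | 0.001 | K | keeps the log-ratio away from noise |
| smoothing | 3 | samples | one-sample noise suppression before argmax |
| `q_amp` | 3.2 | K cm² | gives a ~1.5 K downstream peak at zero flow |
| noise σ | 0.01 | K | realistic thermistor/ADC noise |
| quantisation | 0.005 | K | 16-bit ADC step on a 10 kΩ divider |
| wound `B` | 1.0 | — | no correction; a loud warning asks for the value matching the actual drill/probe diameters |

Annulus boundaries are placed at midpoints between adjacent sensor depths,
with the outer boundary at the sapwood radius and the inner at the
heartwood boundary (both from the config). The Steinhart–Hart defaults are
fitted to a generic 10 kΩ NTC curve (32650/10000/3603 Ω at 0/25/50 °C);
the divider topology (thermistor in the lower leg, read across the
thermistor) is a config enum because logger firmwares differ.

## What the simulator does and does not emulate

It reproduces the trace *shape* physics (conduction–convection transport,
finite pulse, sampling, noise, quantisation, optional linear baseline
drift) and is therefore a valid oracle for estimator correctness and noise
propagation. It does **not** model finite probe diameter, the wound
region, anisotropic diffusivity, radial velocity gradients within one
depth, stem boundary effects, or ambient transients — so passing tests
demonstrate correctness of the estimators under the ideal-medium
assumptions those estimators themselves make, not accuracy on real wood.
On real stems, errors from probe misalignment, wounding and `k`
misspecification dominate, which is why `B` and `k` are user inputs.

## Numerical choices

* Quadrature: `scipy.integrate.quad`, relative tolerance 1e-8; the
  integrand endpoint at zero age is excluded by an epsilon shrink.
* Peak refinement is clipped to ±1 sample; a flat-topped discrete peak
  keeps its sample time (no 0/0).
* Finite-pulse peak times in the oracle are bracketed from the
  instantaneous closed form and solved by Brent's method (xtol 1e-10).
* Internal velocity unit is cm s⁻¹; all reporting is cm hr⁻¹ (×3600).
* Per-cycle noise seeds are derived from the base seed by a fixed affine
  map modulo 2³¹−1, so multi-cycle files are reproducible end to end.
* Results CSV floats are written at 6 significant digits; identical input
  and config produce byte-identical output (timestamps come from the
  input file, never the wall clock).

## Known limitations

* Tmax single-measurement scatter is intrinsically a few cm hr⁻¹ at
  0.01 K noise because the peak is flat near `t_m`; medians across
  repeated cycles are accurate (the test suite checks median recovery
  within 5% at 36 and 100 cm hr⁻¹).
* Very fast flow (≳ 200 cm hr⁻¹ at x = 0.5 cm, k = 2.5×10⁻³) pushes the
  upstream rise below the floor; β is then undefined and the pipeline
  goes straight to Tmax, as it should, but HRM cross-checking is lost.
* `k` must normally be supplied; misspecified `k` biases HRM linearly and
  Tmax through the radicand. An experimental helper
  (`estimate_k_zero_flow`) fits `k` from the late-time cooling of a known
  zero-flow cycle, but any residual advection biases it upward — use it as
  a sanity check, not a calibration.
* The logger CSV dialect is this package's own versioned convention
  (header-tagged); other firmware layouts need a converter.
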