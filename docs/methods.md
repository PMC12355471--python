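# Methods

## Scope

`nanofcs` covers the quantitative arm of a nanodisc-characterization
workflow: binned photon-count traces (measured or simulated) →
autocorrelation → 3D-Gaussian diffusion-model fit → physical quantities
(diffusion coefficient, hydrodynamic size, molecular brightness,
oligomeric state, concentration) → before/after native-PAGE comparison.
Wet-lab stages (solubilization, gel electrophoresis, band extraction, SEC)
are outside the package; their outputs enter only as numbers.

## Diffusion model and fitting

The fitted model is the standard single-component free-diffusion
autocorrelation for a 3D Gaussian observation volume,

    G(τ) = offset + (1/N)(1 + τ/τ_D)^-1 (1 + τ/(S² τ_D))^-1/2 ,

with occupancy N, residence time τ_D = w_xy²/(4D), and structure parameter
S = w_z/w_xy. No triplet-state factor is included by default; dark-state
kinetics are a separate photophysical process and the simulator does not
generate them. A standard triplet factor is available behind an explicit
flag (`fit_curve(..., triplet=True)`) for sensitivity checks on measured
curves.

Fitting is weighted least squares (lmfit/trust-region-reflective, weights
1/sd per lag when the curve carries standard deviations, uniform
otherwise), with all free parameters bounded positive and convergence
tolerances of 1e-10 so fits reproduce across platforms. Starting values
are data-driven — N from 1/max(G), τ_D from the half-maximum lag — so the
default path needs no user guesses. S is free only when fitting the
calibration dye; for sample curves it is fixed at the calibration value,
the usual practice to avoid amplitude/shape degeneracy on noisy curves.
An all-zero sd column is treated as absent (it carries no weighting
information); a non-convergent minimization raises with the iteration
diagnostics rather than returning silently.

Calibration follows the free-dye route: fit the dye curve with S free,
then w_xy = sqrt(4 D_dye τ_D,dye) from a user-supplied literature D_dye,
and V_eff = π^{3/2} w_xy² (S w_xy), maintained as an exact dataclass
invariant. Replicate fits are pooled as per-parameter mean ± sample SD
(the convention for reporting averages of ≥3 independent measurements);
fewer than three replicates yields a result flagged `under_replicated`.

## Correlators

The multi-tau estimator evaluates m = 16 linear lags at the base bin
width, then per level rebins the trace pairwise (bin width doubles) and
adds m/2 lags, until fewer than 2m bins remain — the standard
quasi-logarithmic grid spanning microseconds to seconds at O(N log N)
cost. Every level applies the symmetric-normalization estimator

    G(k) = <x_i x_{i+k}> / (<x>_left <x>_right) − 1

literally to the rebinned trace, where the left/right means run over the
valid overlap only; this removes the finite-trace bias of global-mean
normalization and makes each level bit-identical to the brute-force
estimator applied to an externally rebinned trace — the equivalence the
test suite asserts at 1e-12. Lag zero is excluded (shot-noise dominated,
never fitted). A zero-mean trace is rejected rather than normalized.

## Simulator

The generator emulates the fluorescence fluctuations of labeled nanodiscs
diffusing through a confocal volume:

* Point emitters take Gaussian random-walk steps with per-axis standard
  deviation sqrt(2 D Δt) in a periodic box; default Δt = bin width = 1 μs,
  durations of seconds.
* The detection profile is a 3D Gaussian with 1/e² radii
  (w_xy, w_xy, S·w_xy) — exactly the profile the fitted model assumes, so
  model misfit is never confounded with simulator mismatch. Defaults
  w_xy = 0.33 μm and S = 5 give V_eff ≈ 1.0 fL, consistent with the
  instrument class the reference measurements imply (τ_D ≈ 820 μs at
  D ≈ 33 μm²/s).
* Bin counts are Poisson with mean intensity × bin width. For a 3D
  Gaussian profile the spatial average of the detection weight over V_eff
  is 2^{-3/2}, so the apparent (FCS) brightness equals
  peak_brightness · 2^{-3/2}; `peak_for_apparent_brightness` converts in
  the other direction, and ground-truth records store both.
* The box must span ≥ 6 1/e² radii per axis (default 2 × 2 × 10 μm), which
  keeps direct periodic-image detection weight below 1e-8 of peak.
* The particle number per species is **fixed within a replicate** at the
  stochastic rounding of C·N_A·V_box (floor, plus one with probability
  equal to the fractional part) rather than Poisson-drawn. This
  suppresses replicate-to-replicate variance at desk scale while keeping
  the mean density across replicates exactly equal to the requested
  concentration — plain rounding would bias sub-nM samples by several
  percent in boxes of tens of femtolitres (0.16 nM in a 40 fL box is 3.85
  particles). The remaining documented cost: occupancy fluctuations
  (hence G(0)) shrink by (1 − V_eff/V_box), ≈ 2.5% at the default box.
* All randomness flows from one explicit seed through a single Philox
  generator; identical seed ⇒ bit-identical trace. The inner loop
  (position update, periodic wrap, Gaussian weight, accumulation) is a
  numba-compiled kernel; positions accumulate in float64 from float32
  step draws.

Default acquisition settings (durations of 1–30 s, count rates of tens of
kHz, zero background) are declared package conventions chosen to resolve
300–900 μs residence times with adequate statistics in minutes of CPU
time; the reference study reports no acquisition durations, raw count
rates, or background levels to inherit.

What the simulator deliberately omits — triplet blinking, photobleaching,
detector afterpulsing and dead time, a non-Gaussian point-spread function,
refractive-index mismatch, flow — bounds what passing tests show: they
validate the estimator→fit→inference chain under the model's own
assumptions, not robustness to the photophysical artifacts of real
hardware.

### Finite-box effects and the fit window

Two small desk-scale artifacts are worth knowing. First, with the minimal
6× box, a particle recurs through the focus with period ~L²/(4D)
(≈ 30 ms laterally at default settings), adding a slow positive tail to
G; if the additive offset is fitted over lags extending into that regime
the offset–amplitude–τ_D trade biases τ_D low by several percent. The
default fit window for simulated traces is therefore 1 μs – 20 ms
(> 4 decades, ≈ 25 τ_D at production settings), which removes the effect;
enlarging the box does too. Second, the raw G at the smallest lags
carries the usual finite-trace estimator bias of order −τ_c/T plus the
fixed-N amplitude factor above; the amplitude–concentration law is
therefore exact only as V_eff/V_box → 0 and T → ∞, and the corresponding
property test uses a box with V_eff/V_box ≈ 0.6% and 1 s traces.

## Inference layer

* D = w_xy²/(4 τ_D); first-order (delta-method) propagation of the fit or
  replicate SDs throughout, matching mean ± SD reporting.
* Hydrodynamic size: the default is Stokes–Einstein r = k_B T/(6πηD) at
  configurable conditions (defaults T = 298.15 K, η = 0.89 mPa·s — water
  at 25 °C). A second, π-free variant r = k_B T/(12ηD) is always computed
  alongside (`as_printed`), because the reference work typesets the
  relation that way while its own quoted sizes follow 6πη; reports carry
  both so the discrepancy stays visible. The bundled "particle radii"
  reference table is kept verbatim under that heading with an explicit
  note that its values track computed *diameters* (e.g. GlpF 15.4 nm
  tabulated vs 15.05 nm Stokes–Einstein diameter at D = 32.6 μm²/s);
  several rows (NavMs, KvAP, HpUreI) match neither convention exactly,
  consistent with per-session calibrations that are not published —
  agreement is not forced.
* Oligomeric state: ratio of sample brightness to the free-dye ruler
  (default 7.5 kHz), rounded to the nearest integer ≥ 1. The call is
  flagged ambiguous when the ratio deviates from the integer by > 25%
  relative — loose enough to accept the reference calls (3.12 → 3,
  4.4 → 4), tight enough to surface dubious ones; label self-quenching
  and surface effects on quantum yield make brightness an imperfect
  protomer counter, and the flag is the honest signal of that.
* Concentration: C = N/(N_A V_eff) from the fitted amplitude.
* Integrity verdict: before/after differences in τ_D and ε are each
  "compatible" within k·(combined SD), default k = 2. A brightness drop
  > 50% at compatible residence time raises the quenching flag — the
  signature of Coomassie quenching in blue native gels, as opposed to
  disc disassembly (which would move τ_D). Missing SDs degrade to a 10%
  point-estimate comparison marked low-confidence.
* Lipid count: 2 leaflets × annulus area between disc rim and protein
  footprint ÷ area per lipid (default 0.7 nm²). A deliberately coarse
  geometric stand-in (the reference lipid-count method is unpublished);
  it is labeled approximate everywhere and is meaningful only as an
  order-of-magnitude ratio between disc populations (tetramer/monomer
  ≈ 8 vs the reported ~10).

## Problem sizes

Test-suite simulations use a small observation volume (w_xy = 0.2 μm,
S = 3) and 0.1–6 s traces; the recovery checks of the headline quantities
run in the suite at 2.5 s (brightness) and 6 s (concentration) trace
lengths with 10 seeds and 3-standard-error gates. `scripts/acceptance.py`
runs the full-scale versions (ten 10 s traces at 2.8 nM; ten 30 s traces
at 0.16 nM; ten 64-point synthetic curves), chosen as the package's
reference problem sizes. Statistical acceptance gates are 3-SE bands over
fixed seeds, never per-seed assertions.

## Known limitations

* Single-component model only: mixtures are analyzed per separated
  fraction (as after SEC or gel extraction), not decomposed from one
  curve; two-component and anomalous-diffusion fits are out of scope.
* The brightness ruler assumes one label per protomer, complete labeling,
  and no quenching; deviations are flagged, not corrected.
* The fixed-particle-number design makes sub-nM simulated concentrations
  quantized by the box volume (see above); at the default box this is a
  ≤ 4% effect at 0.16 nM and negligible at nM scale.
* No cross-correlation (FCCS), lifetime gating, or vendor raw formats;
  traces and curves are plain delimited text.
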