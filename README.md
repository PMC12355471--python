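# nanofcs

Fluorescence correlation spectroscopy (FCS) analysis for membrane proteins
in polymer (Glyco-DIBMA) nanodiscs — and a Brownian-dynamics photon-trace
simulator that stands in for the microscope so that every stage of the
analysis can be verified against known ground truth.

## Who this is for

Native polyacrylamide gel electrophoresis separates detergent-free
nanodiscs carrying labeled membrane-protein oligomers, but a gel band alone
does not tell you the oligomeric state, the particle size, or whether
electrophoresis left the discs intact. Confocal FCS on the eluted material
does: the fluctuating fluorescence of labeled nanodiscs diffusing through a
diffraction-limited focus encodes particle number, residence time, and
per-particle brightness. This package implements that analysis chain for
anyone characterizing labeled nanodiscs (or any point-like fluorescent
particle) by single-focus FCS.

## The model

The normalized autocorrelation of the detected intensity,
G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩², is fitted with the single-component
free-diffusion model for a 3D Gaussian observation volume with lateral
1/e² radius w_xy and structure parameter S = w_z/w_xy:

    G(τ) = G_∞ + (1/N) · (1 + τ/τ_D)⁻¹ · (1 + τ/(S²τ_D))⁻¹ᐟ²

* **N** — mean particle number in the effective volume
  V_eff = π³ᐟ² w_xy² w_z, hence concentration C = N/(N_A·V_eff);
* **τ_D** — lateral residence time, τ_D = w_xy²/(4D), hence the diffusion
  coefficient D and, through Stokes–Einstein r = k_BT/(6πηD), the
  hydrodynamic radius;
* **ε = ⟨F⟩/N** — molecular brightness; its ratio to the brightness of the
  free single-label dye (the 7.5 kHz "ruler") counts the labeled protomers
  per particle, i.e. the oligomeric state;
* before/after-gel comparison of τ_D and ε yields an integrity verdict
  (size preserved? brightness preserved or quenched?).

w_xy and S come from a calibration fit of a free dye with known D
(w_xy = √(4·D_dye·τ_D,dye)).

The multi-tau correlator (m = 16 points per level, symmetric
normalization) and a brute-force linear-lag oracle estimator are both
included and agree to 10⁻¹² on shared lags. The simulator moves point
emitters by Gaussian random-walk steps in a periodic box, sums 3D-Gaussian
detection weights into an instantaneous intensity, and draws Poisson
counts per bin — so simulated traces have exactly the statistics the model
assumes, with every ground-truth quantity recorded.

## Worked example

```sh
nanofcs report --config analysis/demo_config.yaml
```

simulates three replicate acquisitions each of a GlpF-like tetramer
(apparent brightness 33 kHz, D = 32.6 μm²/s, 2.8 nM) and monomer
(8.5 kHz, 73 μm²/s, 5.6 nM), correlates, fits, and writes
`scratch/demo_run/report.csv`. The same workflow as explicit stages, with
printed narrative, is in `analysis/01...04`. A run of those scripts
printed:

```
tetramer: tau_D = 733 +/- 72 us, N = 1.74 +/- 0.15
monomer:  tau_D = 347 +/- 20 us, N = 3.45 +/- 0.15
tetramer: brightness 31.3 kHz (truth 33.0), D 37.1 um^2/s, diameter 13.2 nm,
          C 2.89 nM (truth 2.80), oligomer state 4 (ratio 4.18)
monomer:  brightness 8.3 kHz (truth 8.5), D 78.6 um^2/s, diameter 6.2 nm,
          C 5.72 nM (truth 5.60), oligomer state 1 (ratio 1.11)
```

i.e. from raw photon counts alone, three 2-second acquisitions per sample
recover the simulated concentrations within a few percent, size the
tetramer disc at ~13–15 nm and the monomer disc at ~6 nm, and call both
oligomeric states exactly.
`analysis/04_reference_tables.py` re-derives sizes, oligomer calls, and
before/after-gel integrity verdicts for the bundled reference measurements
of four channel proteins (GlpF, NavMs, KvAP, HpUreI), reproducing the
published pattern: sizes preserved by all gel modes, brightness quenched
only by the Coomassie-containing blue native gel.

## Layout

* `src/nanofcs/` — simulator (`simulate`), correlators (`correlate`),
  model fitting and calibration (`fit`), physical inference (`infer`),
  reference tables (`fixtures`), file formats and pipeline (`io`), CLI
  (`cli`).
* `analysis/` — numbered narrative drivers over the package.
* `tests/` — pytest suite, including the recovery checks above at reduced
  trace lengths.
* `docs/methods.md` — model, simulator design, numerical choices, and
  known limitations.
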