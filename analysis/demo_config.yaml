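# Demo pipeline run: GlpF-like tetramer and monomer nanodisc samples,
# simulate -> correlate -> fit -> report.
#   nanofcs report --config analysis/demo_config.yaml
seed: 1
out_dir: scratch/demo_run
calibration:
  beam_radius_xy: 0.33     # um
  structure_parameter: 5.0
conditions:
  temperature: 298.15      # K
  viscosity: 0.00089       # Pa s (water, 25 C)
ruler_brightness: 7.5      # kHz, free-dye single-label reference
correlator:
  m: 16
fit:
  fix_s: true
  fit_offset: true
  max_lag: 0.02            # s; below the periodic-image recurrence time
simulation:
  duration: 1.0            # s per replicate acquisition
  time_step: 1.0e-6
  bin_width: 1.0e-6
samples:
  - label: tetramer
    gel_mode: none
    stage: before
    replicates: 3
    species:
      - label: GlpF-like-tetramer
        diffusion_coefficient: 32.6   # um^2/s
        apparent_brightness: 33.0     # kHz (4 labels, with self-quenching)
        concentration: 2.8            # nM
        oligomer_count: 4
  - label: monomer
    gel_mode: none
    stage: before
    replicates: 3
    species:
      - label: GlpF-like-monomer
        diffusion_coefficient: 73.0
        apparent_brightness: 8.5
        concentration: 5.6
        oligomer_count: 1
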