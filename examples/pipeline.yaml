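# End-to-end demonstration: simulate a filament scene behind strong two-sided
# aberrations and multiple-scattering noise, correct it, and refocus +/- 2 um.
grid:
  n: 64
  pitch_um: 0.08
  wavelength_um: 0.515
  na: 0.8
  n_medium: 1.33
scene:
  preset: filaments
aberration_in:
  kind: random
  rms_rad: 1.5
  corr_length: 0.25
aberration_out:
  kind: random
  rms_rad: 1.5
  corr_length: 0.25
illumination:
  n_target: 193          # fills the NA-0.8 pupil of this grid
  pattern: grid
noise:
  gamma: 0.5             # multiple-scattering / single-scattering power
correction:
  tol: 1.0e-3
  max_iter: 30
  tile_rows: 1
  tile_cols: 1
volume:
  enabled: true
  z_min_um: -2.0
  z_max_um: 2.0
  fine_step_um: 0.5
seed: 5
out_dir: runs
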