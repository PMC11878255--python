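beam:
  amplitude: 1.0
  kind: uniform
design_wavelength: 0.478
grid:
  dx: 0.5
  dy: 0.5
  nx: 1024
  ny: 1024
lattice:
  beamlets:
  - R: 100.0
    center:
    - -90.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - -70.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - -50.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - -30.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - -10.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - 10.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - 30.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - 50.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - 70.0
    - 0.0
    delta: 17.0
    f: 2000.0
  - R: 100.0
    center:
    - 90.0
    - 0.0
    delta: 17.0
    f: 2000.0
  method: overwrite
  period: 20.0
metrics:
  aperture_radius: 100.0
  fwhm_y_threshold: 7.0
  min_sep: 10.0
  rel_thresh: 0.15
  z_focal: null
  z_ref: 0.0
output_dir: out
propagator:
  band_limit: true
  leak_warn_fraction: 0.05
  pad_factor: 1
wavelength: 0.488
z:
  start: 500.0
  step: 5.0
  stop: 3500.0
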