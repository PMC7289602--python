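# Annotated run configuration for the axlsfcs CLI.
# Every processing default lives here so that each choice is user-visible;
# delete any line to fall back to the built-in default (same values).

optics:
  omega_g_nm: 207.0        # green 1/e^2 waist (bead calibration)
  omega_r_nm: 251.0        # red 1/e^2 waist
  z0_g_nm: 1035.0          # axial 1/e^2 half-lengths (~5x the waists)
  z0_r_nm: 1255.0
  tag_frequency_khz: 147.0 # resonant-lens frequency (6.8 us period)
  tag_amplitude_um: 3.53   # peak axial excursion at full drive
  drive_fraction: 0.75     # 75% drive -> ~5.3 um scanned span
  pie_window_ns: 12.5      # micro-time gate boundary (green < 12.5 <= red)

sim:                       # used by `axlsfcs simulate` / `axlsfcs all`
  box_side_um: 4.0         # periodic membrane patch
  densities:               # labeled-construct area densities (um^-2)
    R: 30.0                #   receptors carrying only the red construct
    RL: 20.0               #   dual-labeled ligand-receptor complexes
  default_diffusion: 0.35  # um^2/s for every species unless overridden
  eta_g: 1.0               # fluorophore maturation yields
  eta_r: 1.0
  brightness_g: 0.03       # detected photons per fluorophore per us at focus
  brightness_r: 0.02
  background_g_khz: 0.0    # uncorrelated background count rates
  background_r_khz: 0.0
  bleach_g: 0.0            # bleaching probability per crossing at focus center
  bleach_r: 0.0
  duration_s: 60.0
  seed: 0
  # for `axlsfcs all`: split the receptor pool over a concentration series
  # k_d_nm: 1.0
  # c_l_series_nm: [0.17, 0.5, 1.0, 3.0, 10.0, 30.0]

processing:
  line_time_s: 0.5         # kymograph line for display/tracking
  bin_width_s: 1.0e-4      # correlation input bin
  halfwidth: 2             # signal window = ridge +- 2 pixels (5 total)
  bg_offset: 10            # background pixels at ridge +- 10 (~2 um)
  n_pixels: 26             # z pixels over the sweep (~0.2 um each)
  n_membranes: 1           # 2 for vesicle-style data (two ridges)
  subtract_background: true
  smooth_background: true  # six-sine noise filter before subtraction
  bleach_correction: true
  min_fit_lag_s: 1.0e-3    # exclude sub-ms lags from diffusion fits
  max_lag_s: 1.0
  tau_ratio_max: 3.0       # discard scans with deviant green/red times
  tau_bounds_s: [1.0e-3, 1.0]
  qc:
    max_position_sd: 2.0       # pixels: fluctuating-membrane threshold
    max_center_fraction: 0.25  # of the span: off-center threshold
    cluster_mads: 8.0          # bright-cluster spike threshold
    cluster_lines: 2           # ... lasting at least this many lines
    min_signal_to_bg: 2.0      # low-signal threshold

calibration:               # used for the area factor A in the isotherm
  omega_g_nm: 207.0
  omega_r_nm: 251.0

binding:                   # used by `axlsfcs bind` on recorded series
  n_scans: 3               # scans per concentration for `axlsfcs all`
  datasets: []             # - {c_l_nm: 0.5, paths: [scan1.npz, scan2.npz]}
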