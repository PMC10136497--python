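# Example sraiflux configuration.
# Precedence: built-in defaults < this file < CLI flags.
# Pass with e.g.:  sraiflux quantify --config docs/example_config.yaml ...

# Field preparation (focus, projection, background, saturation QC)
prep:
  focus_channel: stable        # channel scored for focus (stable | labile)
  n_slices: 1                  # 1 = analyse the best-focus slice;
                               # 5 = display-style z-projection window
  projection: max              # max | mean (used when n_slices > 1)
  background_strategy: darkest_tile   # percentile | darkest_tile | manual_roi
  background_q: 1.0            # percentile strategy: q-th percentile
  background_tile: 32          # darkest_tile strategy: tile edge, px
  # background_roi: [0, 0, 32, 32]   # manual_roi strategy: y0, x0, h, w
  max_saturated_frac: 0.01     # reject fields with more saturated pixels

# Index computation (segmentation, ratio, sweep, QC)
index:
  k_sigma: 3.0                 # probe-mask threshold, robust noise units
  min_obj_px: 9                # smallest connected component kept
  ratio_smooth_sigma: 0.8      # sub-PSF Gaussian before the division (0 = off)
  min_area_px: 500             # reject fields with less probe area
  max_area_frac: 0.95          # reject near-full-field masks
  # epsilon, r_cap and thresholds are usually set via CLI flags:
  # --epsilon 1.0 --rcap 10 --thresholds 0.5,1.0,1.5,2.0,2.5,3.0,3.5,4.0

# Puncta counting (tandem-reporter mode)
puncta:
  min_sigma: 1.0               # LoG scale range, px
  max_sigma: 4.0
  k_spot: 5.0                  # response threshold, noise units
  overlap: 0.5                 # non-maximum suppression overlap
  t_punctum: 2.5               # quenched/neutral core-ratio cutoff
  min_cell_px: 200             # fallback cell-counter size floor

# Simulator overrides (sraiflux simulate --config ...)
simulate:
  shape: [128, 128]
  n_z: 5
  n_cells: 8
  amplitude: 600.0             # probe emission, detector units
  alpha: 0.4                   # FRET donor attenuation (neutral compartments)
  beta: 1.0                    # acceptor gain
  read_sigma: 3.0              # Gaussian read noise, detector units
  bit_depth: 12
  z_step_um: 1.5
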