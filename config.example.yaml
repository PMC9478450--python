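# heatpulse processing configuration
# Geometry and wood properties must describe the actual installation;
# the values below match the default simulated setup.

geometry:
  x_d: 0.5              # heater -> downstream probe spacing, cm
  x_u: 0.5              # heater -> upstream probe spacing, cm
  depths: [0.5, 1.5, 2.5]   # radial sensor depths, cm from cambium
  sapwood_radius: 3.0   # cm, outer radius of conducting sapwood
  heartwood_radius: 0.0 # cm, inner boundary of conducting sapwood

wood:
  rho_b: 0.5            # dry wood density, g/cm^3
  m_c: 1.0              # moisture content, g water / g dry wood
  c_dw: 1.2             # specific heat of dry wood, J/(g K)
  c_s: 4.186            # specific heat of sap (water), J/(g K)
  rho_s: 1.0            # sap density, g/cm^3
  wound_B: 1.0          # wound correction coefficient; 1.0 = no correction

medium:
  k: 0.0025             # thermal diffusivity, cm^2/s
  t0: 2.0               # heat pulse duration, s (omit to use the file header)

processing:
  hrm_window: [60, 100] # s after pulse start for the HRM log-ratio average
  dt_floor: 0.001       # K; smaller rises are treated as no signal
  smooth_window: 3      # samples, moving average before peak finding
  baseline_sd_qc: 0.05  # K; larger baseline sd flags "unstable-baseline"
  shared_method: false  # true: one mean beta decides HRM/Tmax for all depths
  missing_policy: error # or "drop": skip annuli with no estimate

thermistor:
  # Steinhart-Hart coefficients for a generic 10k NTC (0/25/50 degC fit);
  # override with coefficients for the installed part for calibrated work.
  sh_a: 1.1252566721075903e-03
  sh_b: 2.3472044729782232e-04
  sh_c: 8.563052731505123e-08
  r_fixed: 10000.0      # ohm, divider fixed resistor
  v_ref: 2.5            # V, excitation reference
  divider_topology: thermistor_bottom
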