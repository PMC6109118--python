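# Cariaco Basin calibration constraints and assigned environmental parameter
# ranges for the three-box organic carbon sulfurization model.
#
# Fluxes are fractions of export production f0; S:C ratios are molar fractions
# (0.037 = 3.7 % mol/mol).  "sigma" is the allowed 1-sigma range for the fit.
# The A->B S:C ratio is poorly constrained and is deliberately absent.
constraints:
  c_flux:
    a_to_b: {target: 0.51, sigma: 0.15}
    b_to_c: {target: 0.38, sigma: 0.05}
    c_to_final: {target: 0.30, sigma: 0.08}
  sc:
    b_to_c: {target: 0.020, sigma: 0.005}
    c_to_final: {target: 0.037, sigma: 0.005}
ranges:
  tau_a_weeks: [0.5, 3.0]        # sinking particles, water column
  tau_b_years: [2.0, 500.0]      # sediment-water interface
  tau_c_years: [2000.0, 20000.0] # deeper sediments
  sc_bio: [0.0, 0.01]            # fresh biomass S:C
  sc_rapid: [0.04, 0.05]         # rapid sulfurization product (boxes A + B)
  sc_gradual: [0.01, 0.03]       # gradual sulfurization product (box C)
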