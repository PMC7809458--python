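# Transfer-calibration template.
#
# Stage 1: enamel-phosphate d18O <-> drinking-water d18O.
#   Species-specific drinking-water calibrations are usually published in
#   the direction water -> phosphate (d18Op = slope * d18Odw + intercept);
#   set direction accordingly and the map is inverted exactly on load.
# Stage 2: drinking-water (~precipitation) d18O -> air temperature (degC).
#
# Replace the numbers below with the calibration appropriate to your taxon
# and region (coefficient standard errors and regression residual standard
# errors feed the Monte-Carlo compound error).  The values shipped here are
# SYNTHETIC placeholders of field-plausible magnitude used by the examples
# and simulations; they are not a published calibration.

stage1:
  direction: water_to_phosphate   # or: phosphate_to_water
  slope: 0.64          # permil phosphate per permil water (synthetic placeholder)
  intercept: 22.6      # permil (synthetic placeholder)
  se_slope: 0.0
  se_intercept: 0.1
  resid_se: 0.2        # regression residual standard error, permil
  cov_slope_intercept: 0.0

stage2:
  slope: 1.7241        # degC per permil (synthetic placeholder, ~1/0.58)
  intercept: 25.0      # degC (synthetic placeholder)
  se_slope: 0.03
  se_intercept: 0.4
  resid_se: 0.8        # degC
  cov_slope_intercept: 0.0
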