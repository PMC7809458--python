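# Full-pipeline configuration (see paleoseason.pipeline.RunConfig).
# Generate matching input tables first with:  paleoseason simulate --seed 0 --out data/

enamel_path: data/enamel.csv
sr_path: data/sr.csv
collagen_path: data/collagen.csv
calibration_path: examples/calibration_template.yaml
output_dir: out/

extraction_method: observed   # or: fitted (smoothed-curve extremes)
apply_damping: true
maturation_length: 6.0        # mm of enamel maturing simultaneously (taxon-specific; required)
sample_length: 1.5            # drill-strip height along the growth axis, mm
min_damping_f: 0.3

measurement_sd: 0.2           # analytical d18O reproducibility, permil
n_mc: 10000
seed: 0

sr_baseline_mean: 0.7106      # local bioavailable 87Sr/86Sr (e.g. modern plants)
sr_baseline_sd: 0.0004
sr_k_sd: 3.0

cn_low: 2.9                   # collagen atomic C:N integrity window
cn_high: 3.6

stats_seasons: [summer, winter, mean_annual]
modern_reference:
  T_july: 20.5                # modern reference temperatures, degC
  T_january: 4.9
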