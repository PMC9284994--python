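# Full-pipeline demo configuration for `thermo run --config examples/pipeline.yaml`
out_dir: scratch/demo_run
seed: 7
method: referenced        # or: referenceless
threshold_CEM: 70.0
baseline_temp_C: 37.0
noise_sd_rad: 0.02
drift_coeffs: [0.3, -0.2, 0.15, 0.25, -0.1, 0.2]
grid_shape: [96, 96]      # reduced matrix keeps the demo fast
n_slices: 5
acoustic_power_W: 3.0
sonication_duration_s: 120.0
pattern: "360"
log_level: INFO
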