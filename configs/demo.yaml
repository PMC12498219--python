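
# Demo pipeline configuration: two trial-level subjects plus a 151-patient
# synthetic cohort, analyzed end to end with the default thresholds.
seed: 20240901
out_dir: vhit_out
trials_dir: null
n_signal_patients: 2
n_trials_per_direction: 15
peak_head_velocity: 250.0
pulse_width: 0.04
true_gain: 1.0
noise_sd: 4.0
accel_thresholds:
  HC: 2500.0
  AC: 1500.0
  PC: 1500.0
blink_cutoff: 350.0
saccade_threshold: 60.0
ms_v_max: 500.0
ms_c: 5.0
ms_tolerance: 0.25
cohort_csv: null
n_patients: 151
copy_intercept: 2.0
copy_slope_hc_gain: -4.0
normative_ranges:
  HC: [0.86, 1.20]
  AC: [0.74, 1.23]
  PC: [0.72, 1.29]
rcft_threshold: -2.0
alpha_remove: 0.10
model: plain_mle
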