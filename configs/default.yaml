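# Default pipeline configuration: the full study layout.
# Any field omitted falls back to the library default with the same value.

seed: 2026

sim:
  n_stroke: 66            # stroke-group participants
  n_healthy: 32           # healthy older adults
  n_trials: 30            # goal-directed contractions per participant
  fs: 1000.0              # sampling rate, Hz
  move_window_s: 3.0      # response-window duration, s
  target_force_N: 10.0
  target_time_ms: 180.0
  pulse_width_factor: 0.5   # pulse HWHM as a fraction of time-to-peak
  group_mean_bias:          # multiplicative aiming bias (force, time)
    stroke: [0.97, 1.08]
    healthy: [1.0, 1.0]
  group_trial_sd:           # trial-to-trial SD (N, ms)
    stroke: [1.0, 17.5]
    healthy: [0.55, 10.0]
  drift_per_trial:          # practice trend per trial (N, ms)
    stroke: [0.01, -0.3]
    healthy: [0.01, -0.3]
  participant_mean_sd: [1.3, 23.0]   # between-person SD of the means (N, ms)
  noise_multiplier_range: [0.5, 2.0] # log-uniform latent noise range (4x)
  baseline_noise_sd: 0.05            # additive sensor noise, N
  outlier_rate: 0.02                 # inflated-SD trial probability
  outlier_sd_inflation: 3.0
  covariate_loading: 0.5             # latent noise -> covariate correlation
  covariate_missing_rate: 0.0
  onset_delay_range_s: [0.3, 0.8]    # reaction-time window

onset:
  baseline_window_ms: 100.0
  k_sd: 3.0
  min_hold_ms: 25.0
  absolute_fallback_N: 0.2

stats:
  gating: levene        # levene | pooled | welch
  gating_alpha: 0.05
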