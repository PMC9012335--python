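preset_pp:
  phase: PP
  contraction_rate: 2.4
  rate_jitter: 0.1
  slow_wave_amplitude: 275.0
  amplitude_dispersion: 0.25
  modulation_depth: 0.5
  spike_burst_amplitude: 40.0
  drift_amplitude: 30.0
  noise_sd: 10.0
  mains_amplitude: 20.0
  cardiac_amplitude: 15.0
  cardiac_rate: 1.2
  respiration_amplitude: 25.0
  respiration_rate: 0.25
  sampling_rate: 256.0
  duration: 600.0
  n_channels: 7
  seed: 0
preset_lp:
  phase: LP
  contraction_rate: 0.4
  rate_jitter: 0.1
  slow_wave_amplitude: 600.0
  amplitude_dispersion: 0.25
  modulation_depth: 0.5
  spike_burst_amplitude: 40.0
  drift_amplitude: 30.0
  noise_sd: 10.0
  mains_amplitude: 20.0
  cardiac_amplitude: 15.0
  cardiac_rate: 1.2
  respiration_amplitude: 25.0
  respiration_rate: 0.25
  sampling_rate: 256.0
  duration: 600.0
  n_channels: 7
  seed: 0
n_pp: 11
n_lp: 15
preprocess:
  cutoff_hz: 0.1
  order: 8
  downsample_factor: 8
  segment_duration_s: 300.0
  max_segments_per_recording: 2
  channel: 0
  zero_phase: false
  settle_discard_s: 0.0
band: null
alpha: 0.05
seed: 0
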