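# Example device configuration: 9-14 Hz seizure band, 26.7 uV threshold.
chain:
  sampling_rate_hz: 625.0
  highpass_hz: 6.8
  band_low_hz: 9.0
  band_center_hz: 11.5
  band_high_hz: 14.0
  smoothing_hz: 1.0
  order: 2
classifier:
  threshold_uv: 26.7
  debounce_s: 2.0
  log_resolution_s: 1.0
  log_capacity: 1200
programs:
  nonevent:
    id: P0
    amplitude_ma: 1.0
    frequency_hz: 125.0
    pulse_width_us: 90.0
    recharge: active
  event:
    id: P1
    amplitude_ma: 3.0
    frequency_hz: 125.0
    pulse_width_us: 90.0
    recharge: active
meta:
  patient_label: example
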