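# Device configuration YAML schema

The configuration file is the hand-off artifact from the workbench to the
device. Validation is strict: **unknown keys are errors** (a misspelled key
silently falling back to a default would be a safety hazard for a device
config), numeric fields are type-checked, and all invariants are
re-validated on import. Units are encoded in the key names.

Top-level keys, in order: `chain`, `classifier`, `programs`, `meta`.

## `chain`

| key | type | default | constraint |
|---|---|---|---|
| `sampling_rate_hz` | float | 625.0 | > 0 |
| `highpass_hz` | float | 6.8 | 0 < highpass < band_low |
| `band_low_hz` | float | **required** | < band_center |
| `band_center_hz` | float | midpoint of the band | band_low < center < band_high |
| `band_high_hz` | float | **required** | < sampling_rate / 2 |
| `smoothing_hz` | float | 1.0 | 0 < smoothing < band_low |
| `order` | int | 2 | ≥ 1, per stage |

## `classifier`

| key | type | default | constraint |
|---|---|---|---|
| `threshold_uv` | float | **required** | > 0 |
| `debounce_s` | float | 2.0 | > 0 |
| `log_resolution_s` | float | 1.0 | in [1, 2] |
| `log_capacity` | int | 1200 | ≥ 1 |

## `programs`

Two entries, `nonevent` (id `P0`) and `event` (id `P1`), each with
`id`, `amplitude_ma` (≥ 0), `frequency_hz` (> 0), `pulse_width_us` (> 0)
and `recharge` (`active` | `passive`). Defaults: P0 = 1 mA and P1 = 3 mA at
125 Hz, 90 μs, active recharge. Seizure-diary mode is expressed by giving
both programs identical settings; transitions are still logged.

## `meta`

Free-form mapping for provenance (patient label, tool version, creation
time). Not validated beyond being a mapping.

A complete example is committed at `examples/device-config.yaml`.
Round-trip guarantee: `export_config` followed by `import_config` (and vice
versa) is a field-for-field identity on valid configurations.
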