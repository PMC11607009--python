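{
  "wheels": ["blue", "green", "red", "yellow"],
  "positions_per_wheel": 10,
  "angular_step_deg": 36.0,
  "arm_radii_mm": [60.0, 75.0, 90.0, 105.0],
  "collector_offsets_mm": [0.0, 10.0, 20.0]
}
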