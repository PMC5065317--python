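{
  "v_hold": -60.0,
  "step_range": [-200.0, 150.0, 10.0],
  "step_duration": 150.0,
  "v_tail": -90.0,
  "tail_duration": 100.0,
  "sample_interval": 0.5,
  "pre_step_baseline": 10.0
}
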