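# Example scenario: default study conditions, all three VSA conditions.
# Run:  vsabci simulate -c examples/scenario.yaml -o session/
seed: 2024
conditions: [overt, covert, free]
paradigm:
  reps_min: 10
  reps_max: 15
profiles:
  covert:
    p3_jitter_sd_ms: 60.0
noise:
  rms_uv: 2.5
decoder: tlda
plan: within
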