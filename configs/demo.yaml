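# Demo configuration: full synthetic pipeline at the default study conditions.
schema_version: 1
seed: 7
simulate:
  n_participants: 20
  n_reps: 10
  slope: 4.0
styles:
  steps_per_axis: 5
  target_frames: 150
equilibrate:
  enabled: true
  measure: MF
compare:
  bootstrap_reps: 2000
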