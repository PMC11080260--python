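# Evaluation design settled during evaluability assessment:
# nominal dimension weights, judgment bands, reporting precision,
# and the Likert instrument used for the acceptability dimension.
dimension_weights:
  availability: 35
  compliance: 40
  acceptability: 25
judgment_bands:
  - [0, 60, poor]
  - [60, 75, fair]
  - [75, 85, good]
  - [85, 100, very good]
precision: 1
likert:
  n_items: 14
  item_min: 1
  item_max: 5
  agree_threshold: 4
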