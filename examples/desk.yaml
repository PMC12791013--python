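# Desk-scale end-to-end run on the synthetic mouse-like fixture.
synth:
  preset: mouse8
  n_recordings: 12
  frames: 1000
  seed: 0
split:
  mode: by_recording
  seed: 0
  length: 60
  stride: 30
model:
  backbone: gru
  proba: false
train:
  epochs: 40
  seed: 0
  switch_prob: 0.1
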