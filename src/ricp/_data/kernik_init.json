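{
 "comment": "baseline state of the 'kernik' profile: 1000 s spontaneous leak-free current-clamp initialisation with dynamic [Na+]i/[K+]i (which are then fixed), followed by 60 s settling with the 2 GOhm baseline seal (init_steady_state + 60 s current clamp, rtol=atol=1e-8)",
 "mode": "spontaneous",
 "duration_s": 1000.0,
 "settle_R_seal_GOhm": 2.0,
 "Na_i_mM": 4.323515651080352,
 "K_i_mM": 108.87263545325884,
 "state": [
  -71.73468723391456,
  5.9975208259154436e-05,
  0.3271223620690919,
  4.323515651080352,
  108.87263545325884,
  0.026075576507877493,
  0.2620315955344833,
  0.12489183013560626,
  0.00020376513458907219,
  0.7374777543187898,
  1.0064495940738993,
  0.9999743834580678,
  0.7392334716615716,
  0.3368389022739557,
  0.020437316806912464,
  0.008249306389720615,
  2.2765672319762431e-07,
  0.4216099617190237,
  0.0005140631629568187,
  0.857809249272217
 ]
}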