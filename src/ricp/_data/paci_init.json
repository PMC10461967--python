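{
 "comment": "baseline state of the 'paci' profile: 1000 s spontaneous leak-free current-clamp initialisation with dynamic [Na+]i/[K+]i (which are then fixed), followed by 60 s settling with the 2 GOhm baseline seal (init_steady_state + 60 s current clamp, rtol=atol=1e-8)",
 "mode": "spontaneous",
 "duration_s": 1000.0,
 "settle_R_seal_GOhm": 2.0,
 "Na_i_mM": 12.040417759297132,
 "K_i_mM": 149.49556007929627,
 "state": [
  -38.762591645642594,
  0.00012741509838953567,
  1.0909121254692113,
  12.040417759297132,
  149.49556007929627,
  0.6783225167281389,
  0.05362321730525989,
  0.05362393344376124,
  0.01627558826799039,
  0.9358822072150167,
  0.23035388429577058,
  1.6222332911956223e-05,
  0.138895898993015,
  0.27195069510247455,
  0.08228912209515678,
  0.0004030393131367344,
  5.5794950708331716e-05,
  0.8522934216297563,
  0.11134269765729281,
  0.0163674523874708
 ]
}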