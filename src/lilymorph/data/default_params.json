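{
  "n": 100,
  "s_x1": 0.8,
  "s_x2": 0.02,
  "x_0": 1.0,
  "x_t": 0.2,
  "t_x": 0.2,
  "s_y1": 1.4,
  "s_y2": 0.28,
  "y_0": 3.5,
  "y_t": 1.2,
  "t_y": 0.2,
  "o_max": 45.0,
  "o_min": 45.0,
  "p": -0.01,
  "r_b": 1.0,
  "h_b": 0.5
}
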