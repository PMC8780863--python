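{
  "v_dark": 1.0,
  "v_light": 1.5,
  "K_I": 0.8,
  "h": 3.0,
  "d_M": 0.85,
  "k_s": 1.0,
  "tau": 8.0,
  "d_F": 0.42,
  "v_w": 0.3,
  "k_fw": 0.15,
  "d_Mw": 0.3,
  "k_w": 0.3,
  "d_Wd": 0.3,
  "d_Wl": 0.4,
  "k_act": 5.0,
  "k_rel": 0.25,
  "K_V": 0.05,
  "k_v": 2.0,
  "d_V": 0.25,
  "frq_null": false,
  "wc_null": false,
  "vvd_null": false
}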