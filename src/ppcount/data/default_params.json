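{
  "hue_value": 0.1,
  "hue_width": 0.5,
  "saturation_threshold": 0.5,
  "iwp_high": 230,
  "ip_high": 70,
  "isp_high": 70,
  "isp_low": 0,
  "inp_high": -1
}
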