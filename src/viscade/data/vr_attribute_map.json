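{
  "_comment": "Mapping from VirtualRetina-dialect XML attributes to config fields. Section element name -> {xml attribute -> dotted RetinaConfig field}. Attributes matching an entry in '_ignored_patterns' are skipped with a warning (radially varying blur is not implemented).",
  "_ignored_patterns": ["radially-varying", "radially-variant"],
  "retina": {
    "temporal-step__sec": "dt",
    "spiking": "spiking_enabled"
  },
  "outer-plexiform-layer": {
    "sigma-center__px": "opl.sigma_center",
    "tau-center__sec": "opl.tau_center",
    "sigma-surround__px": "opl.sigma_surround",
    "tau-surround__sec": "opl.tau_surround",
    "relative-weight": "opl.w_surround",
    "amplification": "opl.lambda_opl"
  },
  "contrast-gain-control": {
    "g-leak__Hz": "bipolar.g_leak",
    "amplification__Hz": "bipolar.lambda_bip",
    "sigma-pool__px": "bipolar.sigma_A",
    "tau-pool__sec": "bipolar.tau_A"
  },
  "ganglion-layer": {
    "sign": "sign",
    "value-at-threshold": "i0",
    "threshold": "v0",
    "lambda": "lambda_g"
  },
  "spiking-channel": {
    "g-leak__Hz": "lif.g_l",
    "v-threshold": "lif.v_thresh",
    "v-reset": "lif.v_reset",
    "refractory__sec": "lif.tau_refr",
    "noise-sigma": "lif.sigma_noise",
    "random-seed": "lif.seed"
  }
}
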