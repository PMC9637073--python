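{
  "name": "triticale-anther-culture",
  "variables": ["Ag", "Cu", "CHH_DNMV", "CHH_SV", "GPRE"],
  "paths": [
    {"from": "CHH_DNMV", "to": "CHH_SV", "label": "lambda1"},
    {"from": "Cu", "to": "CHH_SV", "label": "lambda2"},
    {"from": "CHH_DNMV", "to": "GPRE", "label": "lambda3"},
    {"from": "CHH_SV", "to": "GPRE", "label": "lambda4"},
    {"from": "Cu", "to": "GPRE", "label": "lambda5"},
    {"from": "Ag", "to": "GPRE", "label": "lambda6"}
  ],
  "covariances": [
    {"a": "CHH_DNMV", "b": "Cu", "label": "phi1"},
    {"a": "Cu", "b": "Ag", "label": "phi2"},
    {"a": "CHH_DNMV", "b": "Ag", "label": "phi3"}
  ]
}
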