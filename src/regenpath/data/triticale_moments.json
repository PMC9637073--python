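{
  "description": "Published summary statistics of the triticale anther-culture experiment: per-variable means and variances, the Pearson correlation matrix, and the reported path-model estimates. Cu/Ag are induction-medium ion concentrations (uM), CHH_DNMV / CHH_SV are metAFLP de novo methylation and sequence-variation percentages in the asymmetric CHH context, GPRE is green regenerants per 100 plated anthers.",
  "n": 37,
  "variables": ["Ag", "Cu", "CHH_DNMV", "CHH_SV", "GPRE"],
  "means": {"Ag": 22.4327, "Cu": 5.427, "CHH_DNMV": 0.584, "CHH_SV": 8.655, "GPRE": 2.556},
  "variances": {"Ag": 213.363, "Cu": 12.787, "CHH_DNMV": 0.019, "CHH_SV": 0.013, "GPRE": 2.752},
  "correlations": [
    [1.0, -0.181, -0.426, 0.05, -0.201],
    [-0.181, 1.0, 0.32, -0.386, 0.807],
    [-0.426, 0.32, 1.0, 0.247, 0.005],
    [0.05, -0.386, 0.247, 1.0, -0.297],
    [-0.201, 0.807, 0.005, -0.297, 1.0]
  ],
  "reported_estimates": {
    "lambda1": 0.3818,
    "lambda2": -0.0156,
    "lambda3": -5.0385,
    "lambda4": 2.984,
    "lambda5": 0.4792,
    "lambda6": -0.0124,
    "phi1": 0.2656,
    "phi2": -0.8594,
    "phi3": -0.738,
    "var_CHH_DNMV": 0.0205,
    "var_Cu": 13.794,
    "var_Ag": 672.5904,
    "resid_CHH_SV": 0.0082,
    "resid_GPRE": 0.5474
  },
  "reported_standard_errors": {
    "lambda1": 0.1113,
    "lambda2": 0.0043,
    "lambda3": 1.0668,
    "lambda4": 1.2637,
    "lambda5": 0.0407,
    "lambda6": 0.0045,
    "phi1": 0.0407,
    "phi2": 14.6886,
    "phi3": 0.5777,
    "var_CHH_DNMV": 0.0044,
    "var_Cu": 2.9749,
    "var_Ag": 145.0399,
    "resid_CHH_SV": 0.0018,
    "resid_GPRE": 0.5181
  }
}
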