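{
 "description": "Brute-force simulated population Spearman rho between a repressor lncRNA (base cpm 15) and its coding target (base cpm 80) as a function of the latent gain gamma, NB dispersion 0.2, n=200000.",
 "nb_dispersion": 0.2,
 "base_cpm_lnc": 15.0,
 "base_cpm_coding": 80.0,
 "n": 200000,
 "seed": 0,
 "gamma_to_rho": {
  "0.3": -0.2506,
  "0.4": -0.3685,
  "0.5": -0.4734,
  "0.53": -0.5014,
  "0.6": -0.5629,
  "0.7": -0.6334,
  "0.8": -0.6905
 }
}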