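{
  "shape": [32, 32],
  "n_bins": 256,
  "rep_frequency": 80.0,
  "bin_width": null,
  "components": [[2.5, 0.55], [4.5, 0.45]],
  "photons_per_pixel": 600.0,
  "irf": [1.0, 0.3],
  "noise": "poisson",
  "seed": 7
}
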