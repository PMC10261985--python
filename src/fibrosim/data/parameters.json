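{
 "fitted": {
  "tau_forward": [5.7, 86, 97, 116],
  "tau_backward": [10, 51, 208, 526],
  "progressor_fraction": 0.64,
  "alpha": null,
  "beta": null
 },
 "placebo": {
  "tau_forward": [9.3, 68, 52, 374],
  "tau_backward": [10, 51, 208, 526],
  "progressor_fraction": 0.64,
  "alpha": null,
  "beta": null
 },
 "pioglitazone": {
  "tau_forward": [139, 1750, 1570, 374000],
  "tau_backward": [3.8, 7.6, 171, 2140],
  "progressor_fraction": 0.64,
  "alpha": null,
  "beta": null
 }
}
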