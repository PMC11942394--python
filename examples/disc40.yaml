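# Disc in a 40 mM BaCl2 bath with the reference parameter set.
geometry: disc
bath_mM: 40
n_nodes: 600
solver:
  rtol: 1.0e-6
  atol: 1.0e-10
imaging:
  render: false
  pixel_size_um: 10.0
  noise_sigma: 0.05
out_dir: gelfront_out/disc40
label: disc40_example
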