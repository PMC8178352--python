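{
  "comment": "Preset inference bounds for human PSMC fitting: times in generations, N in haploid gene copies.",
  "n_range": [2, 100],
  "t_range": [400.0, 400000.0],
  "M_range": [0.05, 20.0],
  "s_range": [1.0, 1.0],
  "N_range": [100.0, 10000.0]
}
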