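# Reference fit: produced by this package's own fitting run
# (local CMA-ES from the informally explored region, seed 45,
# population 10 x 40 generations at 2000 trials per evaluation,
# Powell polish, objective = the test-trial behavioural summary).
w_ia: 0.386346
w_sa: 1.306927
w_ca: 0.329602
w_ss: 0.097768
w_lat: 1.196044
coh: 2.256237
col: 69.519475
h: 0.888085
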