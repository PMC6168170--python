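# Default parameters of the 2-D bistable toy SDE.
provenance: published defaults [alpha, lam, beta, c, sigma] = [0.5, 0.25, -0.05, 0.5, 0.4]
alpha: 0.5
lam: 0.25
beta: -0.05
c: 0.5
sigma: 0.4
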