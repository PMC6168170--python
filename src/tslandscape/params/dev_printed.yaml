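# Literal parse of the published (undelimited) 16-value rate table.
# NOTE: this set does NOT reproduce the reported three-fixed-point structure:
# for every uniform degradation rate kd the Gata6 balance admits only the
# differentiated (high-G) state.  It is retained for provenance and remains
# selectable, but "calibrated" is the repository default.
provenance: literal parse of the published table; structurally monostable
k0: 0.005
k1: 0.01
k2: 0.4
k3: 1.0
k4: 0.1
k5: 0.00135
k6: 0.01
k7: 0.01
k8: 1.0
k9: 1.0
k10: 0.01
k11: 5.0
k12: 1.0
k13: 0.005
k14: 1.0
kd: 1.0
L: 50.0
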