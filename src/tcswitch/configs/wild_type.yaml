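# Reduced three-species model, wild-type circuit (dimensionless defaults).
# Located by bifurcation scan: monostable (graded) for every kinase rate.
k_k: 1.0
k_p: 50.0
V_0: 5.0e-5
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
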