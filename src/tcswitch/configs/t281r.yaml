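# Reduced model, phosphatase-dead kinase-impaired mutant (kappa = 0.1).
# Bistable at lam = 0.02: kinase-rate window ~ (7e-4, 0.18),
# growth-rate window ~ (0.016, 0.068)  (located by bifurcation_sweep).
k_k: 0.1
k_p: 0.0
V_0: 5.0e-5
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
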