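# Decoupled strain with a weak phosphatase complex (K_d = 10): no
# sequestration, monostable at every induction level (no hysteresis).
k_k: 0.1
k_p: 0.0
V_0: 5.0e-5
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
Q_tot: 1.0
k_cons: 1.0
k_t: 0.5
k_a: 0.1
k_on_p: 100.0
k_off_p: 1000.0
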