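# Six-species model, T281R = make_variant(detailed_wt, T281R):
# kinase-side rates scaled by kappa = 0.1, phosphatase catalysis absent.
k_k: 0.1
k_p: 0.0
V_0: 5.0e-5
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
k_a: 5.0
k_on_t: 0.2
k_off_t: 1.0
k_cat_t: 1.0
k_on_p: 100.0
k_off_p: 2000.0
k_cat_p: 0.0
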