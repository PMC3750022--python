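# Six-species model, wild-type: autophosphorylation + explicit complexes.
# Effective kinase rate  k_on_t * k_cat_t / (k_off_t + k_cat_t + lam) ~ 1 and
# effective phosphatase  k_on_p * k_cat_p / (k_off_p + k_cat_p + lam) ~ 50
# match the reduced wild-type set in the fast-cycling limit.  The phosphatase
# complex is kept in the unsaturated regime (K_M = (k_off_p + k_cat_p)/k_on_p
# = 40, above the ON-state scale) so the bilinear reduced flux is faithful.
k_k: 1.0
k_p: 50.0
V_0: 5.0e-5
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
k_a: 50.0
k_on_t: 2.0
k_off_t: 1.0
k_cat_t: 1.0
k_on_p: 100.0
k_off_p: 2000.0
k_cat_p: 2000.0
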