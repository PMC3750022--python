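# T281R with the constitutive operon promoter deleted (delta = 0.1):
# residual basal transcription extends the bistable growth-rate window
# down to lam ~ 0.0106, so the strain primes less at reduced growth rates.
k_k: 0.1
k_p: 0.0
V_0: 5.0e-6
V_f: 0.2
K_f: 1.0
h: 1.0
lam: 0.02
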