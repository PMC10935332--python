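# Default coupling-prediction coefficients.
# 3J(H,H): generalized Karplus (HLA) sets keyed by the number of
# non-hydrogen substituents on the H-C-C-H fragment, with Huggins group
# electronegativity differences and beta-substituent attenuation.
# 3J(C,H): cosine fit A cos^2 + B cos + C for aliphatic C-C-C-H paths
# (trans coupling ~9.4 Hz, consistent with the large printed C,H coupling
# of xylitol).
provenance = HLA substituent-count sets; Huggins electronegativities; propane-derived CCCH cosine fit
ch = 8.06 -0.87 0.47
hh2 = 13.7 -0.73 0 0.56 -2.47 16.9
hh3 = 13.22 -0.99 0 0.87 -2.46 19.9
hh4 = 13.24 -0.91 0 0.53 -2.41 15.5
dchi_C = 0.4
dchi_H = 0
dchi_N = 0.85
dchi_O = 1.3
beta_correction = 0.14
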