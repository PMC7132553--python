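# One simulation cell: XCI with gamma = 1 and complete maternal imprinting,
# offspring allele frequency 0.2, N = 1000 with 1:1 sexes.
p_f_par: 0.2
p_m_par: 0.2
rho: null
penetrances: {f0: 0.120, f01: 0.120, f10: 0.240, f2: 0.240, m0: 0.120, m1: 0.240}
r_f: 250
s_f: 250
r_m: 250
s_m: 250
seed: 7
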