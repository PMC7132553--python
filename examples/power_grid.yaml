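# Power grid: XCI with gamma = 1 and complete maternal imprinting, the three
# case sex ratios (3:2, 1:1, 2:3) against 1:1 controls at p = 0.2.
alpha: 1.0e-5
reps: 10000
methods: [zxcii, zmax, xcat, sa, fm02, zc, zmfg]
scenarios:
  - {label: "3:2", p_f_par: 0.20, p_m_par: 0.20, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.24, f2: 0.24, m0: 0.12, m1: 0.24},
     r_f: 300, s_f: 250, r_m: 200, s_m: 250, seed: 11}
  - {label: "1:1", p_f_par: 0.20, p_m_par: 0.20, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.24, f2: 0.24, m0: 0.12, m1: 0.24},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 12}
  - {label: "2:3", p_f_par: 0.20, p_m_par: 0.20, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.24, f2: 0.24, m0: 0.12, m1: 0.24},
     r_f: 200, s_f: 250, r_m: 300, s_m: 250, seed: 13}
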