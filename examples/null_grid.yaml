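# Null grid: the six parental allele-frequency pairs of the size study,
# all penetrances at the 0.120 baseline, 1:1 sexes.
alpha: 1.0e-5
reps: 1000000
methods: [zxcii]
scenarios:
  - {label: "p(0.15,0.25)", p_f_par: 0.15, p_m_par: 0.25, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 1}
  - {label: "p(0.20,0.20)", p_f_par: 0.20, p_m_par: 0.20, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 2}
  - {label: "p(0.25,0.15)", p_f_par: 0.25, p_m_par: 0.15, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 3}
  - {label: "p(0.25,0.35)", p_f_par: 0.25, p_m_par: 0.35, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 4}
  - {label: "p(0.30,0.30)", p_f_par: 0.30, p_m_par: 0.30, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 5}
  - {label: "p(0.35,0.25)", p_f_par: 0.35, p_m_par: 0.25, rho: null,
     penetrances: {f0: 0.12, f01: 0.12, f10: 0.12, f2: 0.12, m0: 0.12, m1: 0.12},
     r_f: 250, s_f: 250, r_m: 250, s_m: 250, seed: 6}
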