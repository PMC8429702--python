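v_1bm: 9.18
k_1bm: 1.02
k_1im: 0.5712
v_c1: 0.1
c_m: 1.0
p_m: 8.0
k_1dm: 0.1224
v_l: 0.25
K_l: 50.0
k_2bm: 0.306
q_m: 2.0
k_2dm: 0.051000000000000004
k_2tm: 0.2448
k_3tm: 0.0204
k_3dm: 0.1224
v_4bm: 3.672
k_4bm: 2.2032000000000003
r_m: 3.0
k_4dm: 0.765
k_5bm: 0.2448
k_5dm: 0.0612
k_5tm: 0.459
k_6tm: 0.0612
k_6dm: 0.1224
k_6pm: 0.09179999999999999
k_7pm: 0.0030600000000000002
k_7dm: 0.009179999999999999
k_vs1: 1.5
k_dv1: 1.5
v_1be: 10.26
k_1be: 1.14
k_1ie: 0.6384
v_c2: 1.01
c_e: 3.0
p_e: 9.0
k_1de: 0.13679999999999998
k_2be: 0.34199999999999997
q_e: 2.0
k_2de: 0.056999999999999995
k_2te: 0.27359999999999995
k_3te: 0.022799999999999997
k_3de: 0.13679999999999998
v_4be: 4.104
k_4be: 2.4624
r_e: 3.0
k_4de: 0.855
k_5be: 0.27359999999999995
k_5de: 0.06839999999999999
k_5te: 0.513
k_6te: 0.06839999999999999
k_6de: 0.13679999999999998
k_6pe: 0.10259999999999998
k_7pe: 0.00342
k_7de: 0.010259999999999998
k_vs2: 1.0
k_dv2: 1.0
k_p1: 0.38
K_p1: 6.54
V_d1: 0.35
K_d1: 4.39
v_coe: 0.85
s: 3.0
k_p2: 0.46
K_p2: 1.63
V_d2: 1.0
K_d2: 0.85
k_p3: 0.73
V_d3: 0.72
K_d3: 0.18
k_syn_GRm: 2.9
k_syn_GR: 1.2
r_f: 0.49
k_re: 0.57
k_on: 0.00329
k_deg_GR: 0.06
k_deg_GRm: 0.11
k_T: 0.63
IC50_GRm: 12.0
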