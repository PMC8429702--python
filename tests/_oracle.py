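"""Independent hand transcription of the 23 model equations.

This module is a *second*, deliberately naive transcription of the coupled
SCN-core / SCN-shell / HPA-axis ODE system, written directly from the
published equations before the package's right-hand side was implemented.
It is used only as an oracle in tests and must stay independent of
``scnhpa.model`` (no imports from the package's model internals).

State order (23):
  0 PerCry_mRNA_c   1 PERCRY_c   2 nucPERCRY_c   3 Bmal1_mRNA_c
  4 BMAL1_c         5 nucBMAL1_c 6 CLOCKBMAL1_c  7 VIP
  8 PerCry_mRNA_s   9 PERCRY_s  10 nucPERCRY_s  11 Bmal1_mRNA_s
 12 BMAL1_s        13 nucBMAL1_s 14 CLOCKBMAL1_s 15 AVP
 16 CRH            17 ACTH      18 CORT         19 GR_mRNA
 20 GR             21 DR        22 DRN
"""

from __future__ import annotations

import numpy as np


def oracle_rhs(y, light, p):
    """Time-derivatives of the 23 states; ``p`` is a flat name->value mapping."""
    (pc_m, pc, npc, bm_m, bm, nbm, cb, vip,
     pc_me, pce, npce, bm_me, bme, nbme, cbe, avp,
     crh, acth, cort, grm, gr, dr, drn) = y

    d = np.empty(23)

    # --- SCN core ---
    act_c = cb + p["v_c1"] * vip ** p["c_m"]
    d[0] = (p["v_1bm"] * act_c
            / (p["k_1bm"] * (1.0 + (npc / p["k_1im"]) ** p["p_m"] + act_c))
            - p["k_1dm"] * pc_m
            + p["v_l"] * light / (light + p["K_l"]))
    d[1] = (p["k_2bm"] * pc_m ** p["q_m"] - p["k_2dm"] * pc
            - p["k_2tm"] * pc + p["k_3tm"] * npc)
    d[2] = p["k_2tm"] * pc - p["k_3tm"] * npc - p["k_3dm"] * npc
    d[3] = (p["v_4bm"] * npc ** p["r_m"] / (p["k_4bm"] + npc ** p["r_m"])
            - p["k_4dm"] * bm_m)
    d[4] = (p["k_5bm"] * bm_m - p["k_5dm"] * bm - p["k_5tm"] * bm
            + p["k_6tm"] * nbm)
    d[5] = (p["k_5tm"] * bm - p["k_6tm"] * nbm - p["k_6dm"] * nbm
            + p["k_7pm"] * cb - p["k_6pm"] * nbm)
    d[6] = p["k_6pm"] * nbm - p["k_7pm"] * cb - p["k_7dm"] * cb
    d[7] = p["k_vs1"] * pc - p["k_dv1"] * vip

    # --- SCN shell ---
    act_e = cbe + p["v_c2"] * vip ** p["c_e"]
    d[8] = (p["v_1be"] * act_e
            / (p["k_1be"] * (1.0 + (npce / p["k_1ie"]) ** p["p_e"] + act_e))
            - p["k_1de"] * pc_me)
    d[9] = (p["k_2be"] * pc_me ** p["q_e"] - p["k_2de"] * pce
            - p["k_2te"] * pce + p["k_3te"] * npce)
    d[10] = p["k_2te"] * pce - p["k_3te"] * npce - p["k_3de"] * npce
    d[11] = (p["v_4be"] * npce ** p["r_e"] / (p["k_4be"] + npce ** p["r_e"])
             - p["k_4de"] * bm_me)
    d[12] = (p["k_5be"] * bm_me - p["k_5de"] * bme - p["k_5te"] * bme
             + p["k_6te"] * nbme)
    d[13] = (p["k_5te"] * bme - p["k_6te"] * nbme - p["k_6de"] * nbme
             + p["k_7pe"] * cbe - p["k_6pe"] * nbme)
    d[14] = p["k_6pe"] * nbme - p["k_7pe"] * cbe - p["k_7de"] * cbe
    d[15] = p["k_vs2"] * pce - p["k_dv2"] * avp

    # --- HPA axis ---
    d[16] = (p["k_p1"] * p["K_p1"] / (p["K_p1"] + drn)
             - p["V_d1"] * crh / (p["K_d1"] + crh)
             * (1.0 + p["v_coe"] * avp ** p["s"] / (1.0 + avp ** p["s"])))
    d[17] = (p["k_p2"] * p["K_p2"] * crh / (p["K_p2"] + drn)
             - p["V_d2"] * acth / (p["K_d2"] + acth))
    d[18] = p["k_p3"] * acth - p["V_d3"] * cort / (p["K_d3"] + cort)
    d[19] = (p["k_syn_GRm"] * (1.0 - drn / (p["IC50_GRm"] + drn))
             - p["k_deg_GRm"] * grm)
    d[20] = (p["k_syn_GR"] * grm + p["r_f"] * p["k_re"] * drn
             - p["k_on"] * cort * gr - p["k_deg_GR"] * gr)
    d[21] = p["k_on"] * cort * gr - p["k_T"] * dr
    d[22] = p["k_T"] * dr - p["r_f"] * p["k_re"] * drn

    return d
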