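"""Staged synchronization: switching the couplings on one at a time.

Starting fully uncoupled in darkness (every compartment free-running at
its own period), the VIP coupling is restored first (the shell locks to
the core), then the AVP coupling (the HPA axis locks to the shell), and
finally light sensitivity under a 12:12 cycle (the whole chain entrains
at 24 h).  Actogram onset drift quantifies each stage: a non-24-h rhythm
drifts across the 24-h raster, an entrained one plots vertically.
"""

import numpy as np

from scnhpa import build_actogram, nominal_parameters, period_stats, simulate
from scnhpa.schedules import constant_dark, regular_light_dark

nominal = nominal_parameters()
stages = [
    ("uncoupled (DD)", nominal.uncoupled(), constant_dark()),
    ("+ VIP coupling (DD)", nominal.uncoupled().with_updates(v_c2=1.01),
     constant_dark()),
    ("+ AVP coupling (DD)", nominal.with_updates(v_l=0.0), constant_dark()),
    ("+ light (12:12)", nominal, regular_light_dark()),
]

state = None
print(f"{'stage':22s} {'VIP':>8s} {'AVP':>8s} {'CORT':>8s}   drift h/day (CORT)")
for label, params, sched in stages:
    traj = simulate(params, sched, 120 * 24.0, initial=state,
                    record_from=60 * 24.0)
    state = traj.final_state()
    periods = [period_stats(traj, v)[0] for v in ("vip", "avp", "cort")]
    act = build_actogram(traj.window(traj.t_start, traj.t_start + 40 * 24),
                         "cort")
    onsets = act.onset_times()
    ok = np.isfinite(onsets)
    slope = np.polyfit(np.arange(act.n_days)[ok], np.unwrap(
        onsets[ok], period=24.0), 1)[0]
    print(f"{label:22s} {periods[0]:8.3f} {periods[1]:8.3f} "
          f"{periods[2]:8.3f}   {slope:+6.2f}")

print("\nWith each restored coupling another compartment joins the common "
      "rhythm; only light pins the drift to zero (vertical actogram "
      "columns at exactly 24 h).")
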