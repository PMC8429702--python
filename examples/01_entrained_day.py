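"""Simulate the nominal individual under a 12:12 light/dark cycle and print
the entrained phase map of the main outputs.

Each output locks to the 24-h Zeitgeber; the peak Zeitgeber times (ZT,
hours after lights-on) reproduce the canonical phase relations: clock gene
Per/Cry peaks mid-day in the SCN core, ~3 h later in the shell, VIP peaks
in the late day, AVP around dusk, and corticosterone at dark onset (the
start of a nocturnal animal's active phase).
"""

import numpy as np

from scnhpa import find_peaks, nominal_parameters, period_stats, simulate
from scnhpa.schedules import regular_light_dark

params = nominal_parameters()
traj = simulate(params, regular_light_dark(), 200 * 24.0,
                record_from=150 * 24.0)

print(f"{'output':24s} {'period (h)':>10s} {'peak ZT (h)':>12s}")
for var in ("per_cry_mrna_core", "per_cry_mrna_shell", "bmal1_mrna_core",
            "vip", "avp", "cort"):
    period, sd = period_stats(traj, var)
    peak_zt = find_peaks(*traj.series(var))[-1] % 24.0
    print(f"{var:24s} {period:10.3f} {peak_zt:12.2f}")

print("\nAll outputs at 24.000 h = entrained; CORT peaking at ZT ~12 marks "
      "the onset of the dark (active) period.")
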