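# Methods

## Model

The model couples three limit-cycle oscillators in a feed-forward chain.

**SCN core and shell.** Each is the interlocked positive/negative
feedback clock of the Becker–Weimann lineage: CLOCK/BMAL1 activates
*Per/Cry* transcription; PER/CRY protein accumulates, translocates to
the nucleus, inhibits its own transcription (Hill inhibition with
exponent 8–9) and activates *Bmal1* transcription; BMAL1 protein cycles
through a nuclear and an active (CLOCK/BMAL1) form.  Seven states per
compartment, all concentrations in nM, rates in h⁻¹.  The photic input
enters only the core, as an additive saturating term on *Per/Cry*
transcription, `v_l · L/(L + K_l)` with `K_l = 50`; VIP is produced in
proportion to cytoplasmic PER/CRY in the core and enters the *Per/Cry*
transcription Hill function of both core (`v_c1·VIP^c_m`) and shell
(`v_c2·VIP^c_e`), in numerator and denominator alike.  AVP tracks
cytoplasmic PER/CRY of the shell the same way VIP tracks the core.

**HPA axis.** A Goodwin-type CRH → ACTH → CORT cascade with saturating
degradation terms and receptor-mediated negative feedback: CORT binds
cytosolic GR (`k_on·CORT·GR`), the complex translocates to the nucleus,
represses CRH and ACTH production and GR-mRNA synthesis, and is partly
recycled (fraction `r_f`) back to free receptor.  AVP multiplies the CRH
degradation capacity by `1 + v_coe·AVP^s/(1 + AVP^s)` (`s = 3`):
receptor-saturating inhibitory control of CRH by the SCN.

The three coupling constants `(v_l, v_c2, v_coe)` are the axes along
which virtual individuals differ; setting all three to zero yields the
"intrinsic" uncoupled compartments.

## Parameter provenance and reconstruction

The published parameter table for this model is internally inconsistent
in four places; this implementation reconstructs the working parameter
set from the table's own provenance notes and the published calibration
criteria (synchronized compartments in darkness; entrainment at 24 h
under 12:12 light; intrinsic periods; the phase map with CORT peaking at
dark onset).  All independently estimated constants (the couplings,
`K_l`, Hill coefficients of the coupling terms, VIP/AVP turnover) are
used exactly as printed.  The reconstruction:

1. **Clock constants are ancestor values × scale, unrounded.**  The core
   and shell tables are the ancestor clock model scaled by 1.02 and 1.14,
   printed rounded to two decimals.  The rounding is not cosmetic: with
   the rounded values the core free-runs at 24.35 h and the shell at
   22.29 h.  The defaults here use the exact scaled values
   (`0.56·1.02 = 0.5712` for `k_1im`, etc.; Hill exponents are
   dimensionless and not scaled), giving intrinsic periods of 23.86 h
   (core) and 22.10 h (shell).
2. **Shell intrinsic period.**  The calibration text reports 21.2 h for
   the shell, but a shell that slow cannot be entrained by VIP at the
   printed coupling `v_c2 = 1.01` (the detuning exceeds the VIP
   entrainment range and the entire entrained solution collapses), and
   the text's own "8 % shorter than the core" matches 22.1/23.9, not
   21.2/23.8.  The printed 21.2 is treated as a digit transposition of
   22.1; this package's shell free-runs at 22.10 h and entrains at
   `v_c2 = 1.01` with an entrainment threshold near 0.95, consistent
   with the published population threshold `v_c2 > 0.8`.
3. **Receptor binding rate.**  The table prints `k_on = 0.03`; with it
   the HPA fixed point is stable and the axis does not oscillate at all,
   contradicting every published behavior.  The receptor-dynamics
   lineage value 0.00329 L nmol⁻¹ h⁻¹ is restored (the printed number is
   a rounding of that lineage's 0.0329 family or a dropped-digit typo).
4. **`IC50_GRm` (not printed at all).**  The half-max of nuclear-complex
   repression of GR-mRNA synthesis is absent from the table.  Because
   rhythmic AVP raises the *mean* CRH degradation ~1.5×, the axis's
   effective period at the coupled operating point sits well below its
   uncoupled period; an axis tuned to free-run at 24.2 h uncoupled runs
   near 20.5 h once coupled and can no longer phase-lock.  The published
   intrinsic HPA period (24.2 h at `v_coe = 0`) and the published coupled
   behavior are therefore mutually incompatible, and this implementation
   resolves the conflict in favor of the coupled behavior, which every
   downstream result depends on: `IC50_GRm = 12 fmol/g` is calibrated
   once so that the AVP-driven axis phase-locks 1:1 with a single daily
   CORT peak at ZT 11.8 ("maximum at the onset of the dark period"),
   with a `v_coe` locking window of roughly [0.4, 1.0) around the nominal
   0.85 and an interior optimum of entraining ability near 0.8.  The
   price is that the *uncoupled* axis free-runs at 27.2 h rather than the
   reported 24.2 h; the package reports this honestly.

`k_syn_GR = 1.2` and `k_deg_GRm = 0.11` are the resolved numeric values
of the table rows that define them through initial conditions
(`GR(0) = 540.7`, `GRm(0) = 25.8 fmol/g`, used here only as default
initial conditions).

## Light schedules

The baseline Zeitgeber is a step function: intensity `I` on
`[kT, kT + χT)`, 0 otherwise (`T` period, `χ` photoperiod; ZT 0 =
lights-on).  Events layered on top: permanent phase shifts (a +Δ advance
makes the schedule read the baseline at `t + Δ`; shifts are applied
instantaneously at onset, so the transition day's lit fraction may differ
from χ, as in an abrupt travel event), bounded light/dark inversions
(lit↔dark complement), rotating inversion blocks (inverted block first,
from the rota onset), additive light pulses, and constant-light/dark
regimes.  Schedules are exact piecewise-constant functions; their switch
times are exported to the integrator.  Shifts beyond ±12 h are rejected
rather than silently folded.

## Numerics

The system is smooth and non-stiff at the working rates (fastest
first-order rate 1.5 h⁻¹), so the integrator is a fixed-step classical
RK4, JIT-compiled, with the step grid re-anchored at every light switch
(each constant-light segment is divided into equal steps ≤ 0.05 h, so no
discontinuity is ever smoothed over).  Halving the step changes all
period estimates by < 0.01 h (asserted in the tests); trajectories are
bit-reproducible for identical inputs.  Default initial conditions are
1.0 for SCN species and lineage basal values for the HPA; all analyses
discard a burn-in (≥ 60–100 days) after which the stable limit cycle has
erased the initial condition (asserted by a multi-start test).

**Rhythm analysis** is peak-based throughout ("peaking time" phases, not
cosinor fits): discrete maxima with prominence ≥ 25 % of the signal
amplitude, refined by a local three-point parabola, merged within 6 h
keeping the larger; periods are means of successive peak intervals with
their SD as a stability flag (entrainment = period within 0.05 h of the
Zeitgeber with SD ≤ 0.05 h).  Phase shifts between trajectories are
same-day peak differences reduced to the smallest representative modulo
24 h and unwrapped day-to-day (increments assumed < 12 h), advances
positive.  Actogram thresholds are `min + 0.9 · amplitude` over the
analyzed window.

## Protocols

* **PRC**: acclimate to darkness to the free-running cycle, anchor CT 12
  at a CORT peak, deliver a 3-h pulse at 12× baseline intensity at each
  CT (grid of 24), and read the asymptotic peak-time difference against
  an unpulsed control.  The model's PRC is type I (continuous, max
  adjacent-CT jump < 2 h) with zero response at zero pulse intensity.
  The delay region falls at CT ~2–12 and the advance region at CT ~14–24,
  the placement required for self-consistency: a clock with τ < 24 h
  whose CORT peaks at ZT 12 must receive net delay from light on
  ZT 0–12.  There is no dead zone (the model has no photic gating).
* **Arnold onions**: a grid over Zeitgeber period × photoperiod; each
  point runs 60 forcing cycles of burn-in plus 16 of analysis, and a
  variable is entrained iff its period matches the Zeitgeber within
  0.05 h with a stable cycle.  The scan Zeitgeber strength defaults to 3:
  at the baseline intensity 1 the photic term (saturating with
  `K_l = 50`) is so weak that the whole onion is ~1 h wide and the three
  compartments are indistinguishable; 3 is the strongest forcing that
  keeps the nominal (24 h, χ = 0.5) point entrained for all outputs.
  Doubling the grid resolution changes areas by < 5 %.  Onion-area
  differences between neighboring compartments measure entraining
  ability; a flat minimum of the AVP–CORT difference curve is reported
  as its midpoint.
* **Jet lag**: permanent shifts of +1…+12 and −1…−11 h at day 100 after
  entrainment, 100 days of follow-up against an unperturbed control.
  Adaptation direction is the sign of the unwrapped CORT shift series;
  resynchronization is crossing 5.8/6 of the adaptation path actually
  taken (|Δ| when shifting the imposed way, 24 − |Δ| otherwise),
  generalizing the published 5.8-h criterion for the 6-h schedule.  The
  phase delay index counts delay-adapted schedules (≤ 11 possible).
* **Shift work**: the transient protocol inverts the schedule for 8 days
  and reports the maximal |CORT phase difference| vs control (wrapped
  representatives, so bounded by 12 h); the rotating protocol (2 days
  inverted, 5 normal, repeating from day 75) classifies an individual as
  group B iff the mean CORT period over ≥ 18 weeks stays within
  24 ± 0.05 h with SD ≤ 0.05 h, else group A.
* **Virtual population**: Sobol triples over `v_l ∈ [0, 0.5]`,
  `v_c2 ∈ [0, 2]`, `v_coe ∈ [0, 2]` (ranges centered on the nominal
  values; scrambled, seeded, reproducible).  A candidate is accepted iff
  it entrains and its ZT-aligned CORT cycle deviates pointwise from the
  nominal cycle by at most 20 % of the nominal amplitude.  The
  amplitude-scaled band is a deliberate choice: a pointwise *relative*
  band collapses at the CORT trough (~0.07 µM) and empirically accepts
  no candidate but the nominal itself, which would void the population
  analysis.  Default desk-scale design: 256 candidates; the test suite
  and examples use 64.

## What the synthetic fixtures do and do not show

The `synth` generators (sinusoid, square, drifting, with seeded Gaussian
noise) validate the rhythm-analysis layer against known ground truth:
period recovery to 0.01 h noiseless and 0.05 h at noise SD 0.05, phase
shifts, actogram drift slopes.  They emulate clean, stationary,
single-component rhythms; they do not emulate waveform asymmetry,
amplitude drift, or measurement gaps of real hormone assays, so passing
them certifies the analytics on model output, not on laboratory data.

## Known limitations

Single-cell (mean-field) SCN compartments; no ultradian glucocorticoid
pulsatility; no glucocorticoid feedback onto the SCN; light is the only
Zeitgeber.  Constant light shortens the period (the model does not follow
Aschoff's first rule for nocturnal animals), and the PRC has no dead
zone.  The uncoupled HPA period exceeds its published value as a direct
consequence of the `IC50_GRm` resolution described above; the alternative
(tuning the uncoupled period) makes corticosterone quasiperiodic under
every light schedule and was rejected.  Problem sizes in the tests and
the acceptance script (64-candidate cohorts, 33×5 onion grids, 0.1-h
`v_coe` steps) are desk-scale choices that keep every protocol in the
seconds-to-minutes range; the library accepts larger designs unchanged.
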