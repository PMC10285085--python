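# Methods

## Model structure

The simulator couples three layers, integrated as one 7-dimensional hybrid
ODE system with state (C_s, x_c, n, f_W, f_S, f_SCN, H_s):

1. **Circadian pacemaker** — a modified Van der Pol oscillator (stiffness
   μ = 0.23, intrinsic period τ_x = 24.2 h) driven by a photic process
   with activated fraction n, activation α(I) = α₀(I/I₀)^p
   (α₀ = 0.05 min⁻¹, I₀ = 9500 lux, p = 0.5), recovery β = 0.0075 min⁻¹,
   gain G = 33.75 and circadian gating (1−0.4C_s)(1−0.4x_c).  The factor
   0.99669 in the stiffness term compensates the period lengthening caused
   by the nonlinearity, so the realized free-running period equals τ_x
   (measured: 24.200 h in darkness).
2. **Sleep-wake flip-flop** — wake, sleep and SCN firing-rate populations
   with sigmoidal steady-state responses (maxima 6, 6, 7 Hz; time
   constants 23, 10, 0.5 min), mutual wake/sleep inhibition
   (g_sw = 0.2508, g_ws = 0.25), SCN coupling (g_scnw = 0.01,
   g_scns = 0.07), and a sleep homeostat H_s ∈ [0, 323.88] %SWA with rise
   constant τ_hw = 946.8 min and fall constant τ_hs = 202.2 min that
   lowers the sleep threshold via β_S(H_s) = −0.005·H_s − 0.0118.
3. **Pain sensitivity** — H_p relaxing between LA = −0.5088 and
   UA = 0.4125 (z-scores of VAS pain intensity) with the homeostat's time
   constants, plus C_p(t) = 0.3411·C_s(t − 720) + 0.03.  Total pain is the
   exact sum P = H_p + C_p.

All times are minutes; illuminance is lux.  Simulation time t = 0 is
clock 08:00 (habitual wake onset), and per-day metrics use 08:00-anchored
windows, matching the protocol day labels.

## Hybrid-system semantics

The behavioral state is a discrete flag rather than a Heaviside of f_W
inside the right-hand side: integration halts at each threshold crossing
of f_W through θ_W = 4 Hz (scipy event detection, direction-aware), the
flag toggles, and integration resumes.  This makes bout bookkeeping exact
and removes any possibility of branch chattering while f_W hovers near
threshold.  H_p is evaluated analytically per bout from the event log, so
it is continuous by construction and exact on the output grid.

During *forced wakefulness* the flag is clamped to wake (homeostat and
pain homeostat use their wake branches) and a constant excitatory input of
magnitude g_sw·S_max = 1.5048 is added to the wake population's net input.
This offsets the largest possible sleep-population inhibition, so f_W
stays above threshold for the whole forced interval regardless of sleep
pressure; at release the input is removed and the natural dynamics decide
whether sleep follows immediately (release near the SCN firing minimum) or
only hours later (release near the SCN maximum — the "can't nap at midday"
behavior).  The forcing mechanism itself is a modeling choice; only its
clamping property (wakefulness guaranteed, natural dynamics at release) is
relied on.

## Numerics

* Adaptive stiff-capable integration (LSODA; τ_SCN = 0.5 min makes the
  system mildly stiff), rtol = atol = 1e-8, max step 120 min, dense output
  sampled on a uniform 1-min grid.
* Integration segments are split at every light-schedule and forcing
  discontinuity, so piecewise-constant light is seen exactly — no
  smoothing at lights-on/off.
* Threshold crossings are located by the integrator's root-finding;
  the array-based `detect_transitions` (linear interpolation on the output
  grid) reproduces them to well under 0.1 min and is used for
  post-hoc analysis of sampled trajectories.
* Daily peak times (C_s, P) are refined by local quadratic interpolation
  around the per-window argmax, giving sub-minute resolution on the 1-min
  grid.
* Fixed-period sinusoid fits use the linear sin/cos parameterization and
  ordinary least squares; amplitude/phase are recovered by
  `hypot`/`atan2`, avoiding nonlinear optimization and phase wrapping.
  A flat series degenerates to amplitude 0 with phase 0 by convention.

## Spin-up and initial conditions

No published initial conditions exist for this system, so every protocol
is preceded by a spin-up under a repeating 24 h light cycle: 20 days,
starting from (C_s, x_c, n) = (−1, 0, 0.5), (f_W, f_S, H_s) = (6, 0, 100),
awake, at clock 08:00.  Twenty days brings the day-to-day drift of the
C_s peak below 1 min/day (0.5 min at 20 days for the 12:12 indoor cycle)
and the entrained periodic orbit erases the initial state (verified by a
test starting from two different states).  Protocols carry their own
spin-up cycle:

* baseline and sweep protocols spin up under their own light cycle;
* the constant-routine protocol spins up under a standard 12:12 indoor
  day (600:0 lux, lights-on 08:00), because its own 0.5-lux laboratory
  lighting is photically too weak to entrain a 24.2 h oscillator; the
  entrained phase this produces puts the C_s minimum at ~03:00, matching
  the experimental timing of the pain-sensitivity maximum and the
  core-body-temperature minimum;
* jet-lag and chronic-restriction protocols spin up under the 12:12
  origin/control day.

## Calibration of the circadian pain map

The affine map from C_s to C_p is derived by fitting fixed-period (24 h)
sinusoids to (a) the simulated C_s over the 58 h constant-routine protocol
and (b) the experimentally identified circadian pain component, then
matching amplitudes (gain), midlines (offset) and fixing the delay at
12 h — the phase relation implied by the coincidence of the pain maximum
and the temperature minimum at ~03:00 — rather than at the difference of
the fitted phases (724 min).  Composing the map with the C_s fit therefore
reproduces the pain fit's amplitude and midline exactly and its phase to
4 min.

With the parameters above, the converged entrained simulation yields a C_s
fit of amplitude 1.024, phase 58 min and midline 0.004 over the 58 h
window.  The oscillator's limit cycle swings ±1.118 at μ = 0.23, and the
fitted amplitude and midline are insensitive to the spin-up schedule
(amplitude 1.007–1.025 across every schedule and window tried); the
published calibration amplitude 0.9968 and midline 0.0235 are consistent
with a trajectory that had not yet converged to the limit cycle, which
cannot be reconstructed without the original initialization.  The fitted
*phase* — the physiologically meaningful quantity — is reproduced to
~2 min.  The derived gain and offset are taken from the published
amplitude/midline pairs, reproducing 0.3411 and 0.030.

## Protocol conventions

* **Baseline**: repeating light:dark day, lights-on 08:00.  The reference
  entrained condition is 14:10 at 600:0 lux (wake 16.71 h, sleep 7.29 h).
* **Constant routine**: day 1 with 0.5 lux 08:00–24:00 and darkness
  24:00–08:00, then 34 h of forced wakefulness at 0.5 lux ending 18:00 on
  day 3, then a 12:12 recovery schedule at 0.5 lux (default 4.5 days).
  The matched control is the identical light schedule without forcing.
* **Deprivation sweep**: 12:12 at 600:0 lux; protocols are labeled by
  total time awake including the ~12 h habitual wake; the forced window
  starts at the *model's* entrained wake onset (~07:42 for this baseline),
  not at a fixed clock hour.
* **Jet lag**: 12:12 origin day at 600:0 lux; at 08:00 origin time on day
  3 the schedule steps to the destination's 12:12 day shifted 5 h earlier
  (east) or later (west).  Destination lux mirrors the origin (the minimal
  symmetry assumption).  In-flight deprivation, when enabled, is an 8 h
  (east) or 11 h (west) forced-wake interval ending at the switch.
  Re-entrainment is declared on the first day from which the daily C_s
  peak difference stays within 0.5 h of the 5 h target.
* **Chronic restriction**: 7 days with forced wakefulness outside
  04:00–08:00, 600 lux indoor light while awake and darkness in the sleep
  window.  The control is the unrestricted 12:12 600:0 day.

## Known limitations

* Single deterministic subject: no inter-individual variability, no noise,
  no statistical testing.
* Sleep is a single state — no REM/NREM architecture, no orexinergic
  arousal system; wake/sleep transitions are sharp threshold events.
* Pain modulation is feed-forward only; painful states do not feed back on
  sleep or the clock, and non-photic circadian inputs are absent.
* The pain scale is a relative z-score of VAS intensity; absolute
  behavioral significance of a given change is outside the model.
* Forced wakefulness is idealized (perfectly effective, instantaneous
  release); real deprivation protocols involve micro-sleeps and variable
  compliance.
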