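# Methods

## Scope and intent

`respassist` is a desk-scale simulator: every component of the
robot-assisted-expiration control problem — lung mechanics, actuator
transmission, dual-layer controller, pneumatics, sensing — is modelled
explicitly, and virtual subjects replace human participants. The goal is
to make the *control architecture and its analysis pipeline* exercisable
and testable end to end, not to predict absolute human outcomes.

## Lung mechanics

The respiratory system is a single-compartment resistance–elastance
plant on the tidal excursion v (expired volume, L):

    R·dv/dt + E·v = Pmus + Pexo

Expiratory flow is positive; inspiration is negative flow. The
absolute-volume formulation (residual volume, PEEP) reduces to this tidal
form under the static balance E·Vlung0 + P_PEEP = 0; residual volume and
PEEP are carried in `LungParams` for completeness but never enter the
simulated dynamics.

The expiratory waveform family lives on the normalized phase θ ∈ [0, 1]:
flow Q(θ) = Q₀·sin(πθ), phase-domain volume V(θ) = −(Q₀/π)·cos(πθ)
(integration constant zero: volumes referenced to mid-expiration), and
muscle pressure Pmus(θ) = A·sin(πθ+φ) with A = Q₀·√(R²+(E/π)²),
φ = arctan(−E/(πR)) < 0 (pressure leads flow). Note that V(θ) integrates
over θ, not time, so A is rate-independent by construction; the
physical expired volume of a half-sine expiration of duration Tₑ is
2·Q₀·Tₑ/π (`physical_tidal_volume`).

### Discretisation

`simulate_plant` and the closed loop use the trapezoidal (bilinear)
discretisation of the first-order plant, with flow read out from the
pressure balance, Q_k = (P_k − E·v_k)/R, rather than differenced. Two
identities then hold exactly (to rounding) at the sample rate:

1. pressure balance: R·Q_k + E·V_k = Pmus_k + Pexo_k at every sample;
2. conservation: (Q_k + Q_{k+1})·Δt/2 = V_{k+1} − V_k.

Classical RK4 is available (`method="rk4"`) and agrees with the closed
form to the same order, but under RK4 the two identities above cannot both
hold at the sampling grid (trapezoidal quadrature of a smooth flow differs
from the exact integral by ~4×10⁻⁶ L per breath at 200 Hz), so the
trapezoidal scheme is the default: it makes volume bookkeeping and the
identification algebra exact by construction. For a first-order linear
plant with time constants ≥0.15 s sampled at 200 Hz, both schemes are far
below any tolerance of interest (step-response error <10⁻⁶ relative at
1 ms steps).

## Transmission

Supply pressure to belt force is affine, Fa = α_t·Psup + μ, fitted
per subject by OLS over the rated 0–20 kPa range (`calibrate_transmission`
reports R², Pearson r and standard errors; a flat force response is
flagged degenerate with undefined r). Belt force to lung pressure is
linear, Pexo = δ·Fa, where δ = k_th·C_ab·η/(A·V₀) lumps the
abdominal–diaphragmatic–thoracic cascade; the stepwise cascade is kept as
an independent code path and checked against the lumped coefficient.

Units: airway pressures are in cmH₂O, actuator pressures in kPa
(1 kPa = 10.1972 cmH₂O). δ crosses that boundary and is therefore stored
with an explicit unit tag. The published range for δ (0.1–0.5 kPa/N,
i.e. ≥1 cmH₂O/N) is mutually inconsistent with the 30 cmH₂O airway
ceiling once the belt pretension μ (50–110 N) engages — the pretension
alone would contribute ≥50 cmH₂O. The virtual cohort therefore draws δ
from 0.008–0.02 cmH₂O/N, chosen on two grounds: peak Pexo at the rated
400 N stays well below the ceiling, and the reference force
Fa_ref = Pexo_ref/δ for physiological pressure amplitudes (1–4 cmH₂O)
lands inside the device's working range (tens to ~300 N), keeping the
force-planning loop in its linear region. The literal kPa/N range remains
selectable for unit-fidelity checks with the safety clip active.

μ is implemented as a force offset in newtons (an affine force law
demands it, whatever unit its published table row carries).

## Controller

**Phase estimation.** Binary inspiration/expiration segmentation by
hysteresis on the smoothed measured flow (default hysteresis 2% of Q₀,
5-sample moving average, flip debounce of 20% of the nominal half-period),
then θ = min(1, Vex_cum/Vex_pred) with Vex_pred taken from the previous
completed expiration (optionally exponentially weighted; default pure
previous breath). The first breath, with no prediction available, is a
flagged warm-up with θ pinned to 0 and no assistance.

**High level.** Pexo_ref(θ) = β·A·sin(πθ+φ), floored at 0 (the belt
cannot suck) and clipped so the model-predicted Pmus(θ) + Pexo_ref(θ)
never exceeds 30 cmH₂O. The clip acts a priori on the planned profile;
runtime pressure feedback is not used for this limit. Assistance is cut
(references zeroed) at the sensor rate as soon as the estimated phase
leaves expiration.

**Low level.** Fa_ref = Pexo_ref/δ clamped to [0, 400 N];
Fplan = Fa_ref − B·dFint/dθ − K·Fint clamped likewise (compliance
modulates a commanded force — with a zero reference nothing is planned,
so sensor noise cannot inflate the belt); Psup_ref = Fplan/α_t (gain-only inversion
that drops μ, the published form of the mapping; the exact affine inverse
is available via `exact_inverse`) clamped to [0, 20 kPa]; and the tracking current
I = k₁·Cv·√(Pin − k_P·e − k_D·ė), e = Psup_ref − Psup, with a negative
radicand floored at zero and counted as a saturation event. A closed
valve (I = 0) charges the chamber toward the source pressure — the
feedforward's saturation behaviour is therefore "full charge", which the
PD terms then unwind.

θ-derivatives (of Fint and of the pressure error) are causal first-order
differences of 5-sample moving averages, with the raw quotient
exponentially smoothed (weight 0.3 per controller tick): per-tick phase
increments are of order 10⁻²–10⁻³, and an unsmoothed quotient would
amplify sensor noise directly into the force plan. Outside expiration the
derivatives are held at zero.

**Stability.** The tracking-error argument gives
V̇ = (1−k_P)·x₁² − k_D·x₂² for V = (x₁²+x₂²)/2, i.e. both error
coordinates decay for k_P > 1, k_D > 0. `check_stability` tests the
analytic condition and additionally integrates the error dynamics
numerically, asserting V never increases by more than 10⁻⁹ per step.
Gains are validated against their published ranges at configuration time
(k_P strictly above 1).

## Pneumatics and actuation lag

Valve statics follow the orifice law and the linear current–flow
characteristic, combining to Psup = Pin − (I/(k₁·C_f))² (floored at 0;
C_v of the control law aliases to C_f unless configured). The chamber
fills as a first-order lag (τ_fill = 30 ms default) toward the static
characteristic; `step_dynamics` additionally honours a transport dead
time on the current command, whose pre-history is the holding current of
the initial pressure (a step therefore leaves the output unchanged until
the dead time elapses).

In the closed loop, the measured ~200 ms actuation lag is attributed to
the *elasticity-adjustment mechanics* between chamber pressure and
delivered belt force, modelled as a first-order (viscoelastic) lag with a
200 ms time constant. Two alternatives were rejected on stability
grounds, which we record because the choice is load-bearing: placing the
200 ms as a dead time inside the pressure-tracking loop makes the printed
PD gains linearly unstable (the loop limit-cycles across the full supply
range), and placing it as a dead time on the force path turns the
B·dFint/dθ compliance term into a relay oscillator (derivative feedback
through a pure delay has unbounded phase lag). A first-order lag matches
the measured time scale while keeping the two-pole loop phase bounded,
and is the physically natural model for soft-actuator/tissue mechanics.
Belt pretension engages continuously, Fa = α_t·Psup + μ·min(1, Psup/1 kPa):
a hard engagement threshold for the 50–110 N pretension also produced a
relay limit cycle against the stiffness term K·Fint.

With C_v = C_f, the tracking law settles at Psup = k_P/(1+k_P)·Psup_ref —
a proportional-only offset (~28% at k_P = 2.6) inherent to the published
law; the force plan simply operates around it.

## Closed-loop timing

Simulation and sensors run at 200 Hz; the controller runs at 100 Hz with
zero-order hold; sensor reads carry a one-sample (5 ms) communication
latency. Sessions default to 180 s; the crossover protocol pairs a
natural and an assisted session per (rate, repetition) cell at
12/20/30/40 breaths/min.

## Virtual subjects and noise

A subject bundles a transmission line (α_t, μ from the published
per-subject calibration table or uniform draws over the published
ranges), lung parameters (R ∈ [1.5, 5], E ∈ [2, 10]; the identified
physiological values R = 2.7 cmH₂O·s/L, E = 4.8 cmH₂O/L are the table
default), a breathing pattern (Q₀ ∈ [0.3, 0.6] L/s — half-sine amplitudes
giving normal-range tidal volumes at the tested rates), and noise levels:
flow sensor noise 0.01 L/s SD, interaction-force noise 1 N SD, per-breath
muscle-pressure amplitude jitter with 5% CV, and a 5% breathing-phase
modulation of the contact force. Calibration sweeps add 7 N SD force
noise, which reproduces the published spread of calibration correlations
(Pearson r ≈ 0.96–0.996). All noise is Gaussian and independent per
channel.

The simulated human applies the same Pmus waveform in natural and
assisted sessions (constant effort — the alternative, effort
substitution when assisted, is not modelled). Every random stream derives
from one root seed via seed-sequence spawning, keyed by subject,
repetition and channel but *not* by mode, so a matched pair shares its
physiology and sensor-noise realisations exactly. Two consequences worth
knowing: an assisted session with zero assist gain reproduces the natural
session's physiological channels bit for bit, and the state-difference
identifier benefits from common-mode cancellation of flow-sensor noise in
matched pairs (real paired experiments would not; the noise-robustness
tests therefore use independent noise).

What the generator does not emulate: nonlinear/viscoelastic tissue,
multi-compartment airways, gas exchange, motion artifacts (an optional
burst model exists but defaults off), inter-breath rate drift, and any
behavioural response of the subject to assistance. Passing tests
demonstrate the architecture's correctness and its directional effects
under these idealised conditions, not human effect sizes.

## Identification

`build_design` assembles H = [Q_A−Q_B, V_A−V_B], y = δ·Fa from a matched
pair. Default alignment is sample-by-sample in time: the simulator's
metronome-paced sessions share one clock, making time alignment the exact
degenerate case of the metronome assumption. Per-breath phase-grid
resampling (200 points per breath, linear interpolation, breaths paired
in order) is available for sessions with unsynchronised clocks; it is
intrinsically approximate because it pairs samples taken at different
wall-clock times. Rows whose flow and volume differences both fall below
1% of their respective maxima are dropped (they only inflate
conditioning). The volume regressor is the within-session tidal
excursion (integral of flow), which is what the reduced pressure balance
contains — not a literal minute-ventilation quantity.

`identify_RE` solves the normal equations and always reports cond(H);
ill-conditioning raises an error carrying the condition number rather
than falling back to a pseudo-inverse.

Known limitation: when volume is obtained by integrating noisy flow, the
volume regressor carries a random walk correlated with the flow noise,
and the induced errors-in-variables bias *grows* with session length —
past roughly 500 samples it dominates the shrinking variance, so longer
sessions stop improving the estimate. Consistency in the textbook sense
(RMSE ↓ with n) holds for white noise on the design rows and is tested
that way; the integrated-noise behaviour is asserted separately.

## Metrics

PEF is the session maximum of expiratory flow over complete breaths (a
per-breath-mean variant is available). A breath spans expiration onset to
the next expiration onset, detected offline by the same
hysteresis-plus-debounce segmentation the controller uses online; partial
first/last breaths are discarded, and a record that begins inside the
hysteresis band is taken to begin at an onset. Tidal volume per breath is
max−min of the volume curve; MTV its mean; MV is expired volume over the
complete-breath span normalised to one minute. MV is expiration-side *by
definition* here, with the inspiratory split (MV_i) reported separately —
conventions differ across the literature, so this is stated prominently.
The typed consistency check MV ≈ MTV·rate warns (not errors) beyond 2%;
breath-amplitude jitter plus rectified sensor noise can push realistic
sessions a few percent apart.

Cohort improvement is the arithmetic mean of per-subject percent changes;
significance uses a two-sided paired t-test by default (Wilcoxon
optional), with the conventional star thresholds (0.05/0.01/0.001).
Identical pairs give p = 1; zero-variance nonzero shifts are flagged
degenerate instead of starred.

## Problem sizes

The test suite runs sessions of 10–40 s and a 50-subject stress sweep at
12 s per session; the acceptance script uses 60 s sessions throughout,
including the full 50-subject × 4-rate stress sweep (2.4 M simulated
samples). These sizes were chosen as the smallest that give every
estimator and envelope check many complete breaths per cell; all
reported identities are exact at machine precision and do not depend on
session length.
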