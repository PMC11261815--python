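# Methods

## Model

The plant is a deliberate collapse of a full multibody spine to one
sagittal degree of freedom: a rigid trunk segment (mass 36 kg, joint-to-COM
distance 0.22 m, inertia 2.6 kg·m² about the joint, consistent with a
78-kg, 175-cm adult) rotating about a lumbar hinge.  Four lumped
fascicles act through constant, signed moment arms (extension-positive):
ES +0.055 m, MF +0.045 m, RA −0.08 m, PM −0.04 m.  Muscle-tendon length
is linear in the joint angle, `l_mt(theta) = l_ref + arm · theta_flexion`,
with `l_ref` chosen so each fiber sits at its optimal length in the
upright posture.  Pennation is folded into the lumped line of action
(alpha = 0 by default), so the fiber-force projection and the joint
moment `F_tend · arm` carry no hidden cosine discrepancy.

Default strengths (ES 2500 N, MF 1500 N, RA 1000 N, PM 1300 N) give an
upright maximal extension capacity of ~205 N·m against ~132 N·m in
flexion — extensor-dominant, as trunk dynamometry shows, and the
deliberate *starting guess* that calibration rescales.  Maximum
contraction velocities are 10 optimal lengths per second; at 30 °/s the
force-velocity factor stays within [0.91, 1], so the protocol is
effectively quasi-isometric at the fiber level, which is why the maximum
isometric force is identifiable from it at all.

Remaining joint structures: gravity (−m·g·d·sin θ, extension-positive), a
lumped linear IVD bushing (15 N·m/rad, 1.5 N·m·s/rad — small against the
muscles, representing passive osteoligamentous stiffness near neutral),
and a stiff rotational coupling to the position-prescribed dynamometer
lever (5000 N·m/rad, 50 N·m·s/rad).  The coupling replaces the device's
kinematic constraint; its reaction is the recorded moment, and its
finite stiffness leaves the ~0.5–3° tracking lag a feedback controller
needs.  The coupled mode (ω_n ≈ 44 rad/s, ζ ≈ 0.22) rings for ~0.5 s
after each lever velocity step; this transient appears identically in
the active and passive runs and cancels in M_isom.

Tendon: rigid by default (the slack tendon transmits fiber force
unchanged), which is accurate here because tendon strain at these forces
changes fiber length by <1% of the excursion and the 10-ms control loop
is far slower than tendon dynamics; an elastic mode (Brent root solve of
the fiber-tendon equilibrium, residual ≤ 1e-6·F0) exists behind a flag
and agrees with the rigid mode within ~1% at eps0 = 0.001.  Activation
dynamics time constants default to tau_act = 10 ms, tau_deact = 40 ms
(fast-deactivation-slower-than-activation ordering); tendon strain at F0
defaults to eps0 = 0.04.

## Controller

The activation controller is incremental: each 10-ms step adds
`(PCSA_m / Σ PCSA_group) · (kp·e + kd·de/dt)` to a per-fascicle command;
a positive command drives the extensors (flexors at the 0.02 floor) and
a negative one the flexors, clipped to [0.02, 1].  The error is
evaluated against a 0.5-s *preview* of the reference trajectory — the
neural anticipation of future motion — so during a steady phase the
controller faces a persistent ~15° error that integrates to saturation
within a second: exactly the maximal-effort behavior isokinetic testing
elicits.  A config switch (`feedforward="delay"`) provides the literal
delayed-error reading instead.

Two implementation choices matter and are ours:

* **Derivative along the reference.**  In incremental form the
  derivative term carries an effective proportional gain kd/dt = 500 on
  the error.  Differentiating the raw error feeds the compliant
  coupling's lag straight back at that gain, which limit-cycles the loop
  (activation chatter at the coupling resonance and a net muscle moment
  regulated toward zero).  The derivative channel therefore uses the
  perfect-tracking approximation d/dt[θ_ref(t) − θ_ref(t+τ)], which is
  exactly the anticipatory phase-reversal signal the feedforward time is
  meant to contribute and carries no feedback path.  The proportional
  channel keeps true state feedback.

* **Pre-roll.**  Commands start at zero, so the first extension phase
  would be the only one not preceded by a reversal kick and came out
  systematically weak.  The controller is now stepped over the 0.5-s
  preview window before lever motion begins, with the trunk held at the
  start angle — a braced subject already pushing when the device starts.

## Calibration

M_isom = M_act − M_deact is compared raw against the 6-Hz-low-passed
measured trace.  We deliberately do **not** low-pass the simulated
difference: the zero-phase Butterworth filter undershoots by ~5% of the
preceding plateau after each phase change, and that artifact lobe can
masquerade as (and be calibrated against) a weak flexion peak; the raw
simulated difference is already smooth because the reversal transients
cancel between the active and passive runs.

Beta ratios are taken from the same peak statistic the error metric and
the reported maximum-moment values use: the mean of the first three
per-cycle extrema of the matching movement phase (extension maxima
within extension segments, flexion minima within flexion segments,
segments cut at velocity sign changes of the measured angle).  This
keeps the ratios phase-consistent — with the anticipatory controller the
next phase's agonist switches on ~0.25 s before the reversal while still
lengthening, and an eccentric transient would otherwise set the global
extremum and bias beta_flex low — robust to single-cycle noise, and
makes the converged error exactly |1/beta − 1|.  For well-behaved
waveforms it tracks the plain trace-wide max/min closely.

The update `F0 ← beta·F0` is applied to every fascicle of an
out-of-band group, both groups simultaneously when both are out.  The
peak moment is nearly proportional to F0 (activation saturates; the
passive term is itself proportional), so one update typically lands
beta within a few percent of 1 and the loop converges in 2–3 iterations.
A converged subject whose beta sits at the band edge (beta ≈ 0.8) can
still carry a peak-moment error up to 1/(1−δ) − 1 = 25%: the stop rule
bounds the ratio, not the error, so a sub-20% error cannot be guaranteed
per trial.  Under the synthetic study conditions (strength scales
uniform in [0.6, 1.6], planted antagonist co-contraction, no synergy
modeling) roughly 7–10% of subjects land in that band, so a 20-subject
population typically shows 1–3 converged trials with 20–25% errors —
which is what the population-level claim (≥ 90% of subjects under 20%)
reflects, and why an unlucky population can miss it by one subject.

Dynamic relaxation (near-critical artificial damping, settle to
|ω| < 1e-3 rad/s, residual < 0.01 N·m) provides the initial posture; it
is run once per calibration because rescaling F0 moves the passive
equilibrium by < 0.005 rad through the stiff coupling.  Degenerate
simulations (no positive extension maximum or negative flexion minimum)
raise rather than mis-calibrate; exceeding the iteration cap flags
non-convergence without raising.

Optional fiber-length personalization sets l0 of the ES and RA to the
mean fiber length at the per-cycle peak-moment instants (extension peaks
for ES, flexion peaks for RA); whether the peak length should be the
optimum itself or 0.95·l0 (where the force-length curve actually peaks)
is ambiguous, so both targets are offered with `l0` as default.  It is
off by default in the calibration loop — with near-optimal default
geometry it moves the identified strengths by little, at the cost of a
further simulation pass.

## EMG, synergies, and IAP

The envelope chain is sixth-order Butterworth 10–250 Hz band-pass,
full-wave rectification, fourth-order 6-Hz low-pass, each applied
zero-phase (offline data; doubles the effective order — a single-pass
flag exists), then per-channel MVC normalization over the trial set.
NMF (multiplicative updates, Frobenius loss, 500 iterations, tol 1e-6,
10 seeded restarts, best reconstruction kept) is scanned over the order
until VAF first exceeds 80%.  W columns are max-normalized with the
scale folded into H; group coupling scalars are the mean weights of the
flexor/extensor channels in the flexor-/extensor-dominated columns, and
the antagonist group is activated at `(W_cross/W_own)·a_agonist`,
clipped to [0.02, 1], during the opposing phase.

A known limitation, found with the planted-factor oracle: when every
channel carries co-contraction leakage (no pure channel), the NMF
optimum is a manifold — leakage weights can be "shaved" toward zero
without changing the reconstruction — so estimated coupling ratios run
20–40% below the planted values and synergy-aided strength recovery
retains a residual ~10–25% downward bias.  This is inherent to NMF on
fully-mixed data, not a solver artifact (more iterations and alternative
initializations land on the same error).  Spatial-vector recovery by
cosine similarity (> 0.95 noiseless) is insensitive to it.  Relatedly,
strong planted co-contraction can push VAF(1) over 80%, in which case
the order rule honestly selects S = 1 and the synergy arm is
inapplicable for that subject.

IAP is a piston: pressure × diaphragm area × lever arm as a pure
extension-assisting moment (defaults 10 kPa, 0.01 m², 0.05 m → 5 N·m at
plateau; magnitudes are surrogate values since intra-abdominal pressure
is not measured here).  Within each breathing phase the pressure ramps
up linearly over 0.5 s, holds, and releases over the final 0.5 s.  Its
identifiable consequence at this scale is directional: enabling it
weakly lowers the calibrated extensor F0 needed to match a fixed trace.

## Synthetic subjects

A seeded subject owns per-group strength scales uniform in [0.6, 1.6], a
planted 8-channel × 2 synergy matrix (dominant weights 0.6–1.0,
antagonist leakage 0.1–0.4), 5 N·m Gaussian moment noise (before the
6-Hz measurement filter) and 5% relative envelope noise.  The "measured"
trace comes from a maximal-effort activation *script* (agonist ramps to
1 over 0.25 s each phase; antagonist at the planted leakage ratio) — not
from the PD controller — so identification never trivially inverts its
own forward model.  EMG is the planted W·H(t) envelope (phase-locked
sin² bumps) amplitude-modulating a 10–250 Hz Gaussian carrier.

What the generator does *not* emulate: trial-to-trial fatigue drift,
angle-dependent device compliance, electromechanical delay, crosstalk,
motor-unit statistics, and any 3-D kinematics.  Passing tests therefore
demonstrate that the identification machinery is correct and
well-conditioned under the stated protocol, not that it is accurate on
real dynamometer data; the published real-subject aggregates (Pearson
r, angle RMSE, IAP strength shifts) are replaced by direction and bound
checks on synthetic trials.

## Numerical choices and problem sizes

Fixed-step RK4 at 1 ms inside 10-ms zero-order-held control steps;
lever and IAP signals precomputed on the half-step grid.  Trials are 5
cycles × 4 s; a full calibration (2 simulations per iteration, 2–3
iterations) takes ~2–4 s, and the 20-subject population sweep used by
the tests and the acceptance script ~80 s on one CPU.  Unit tests use
2–3-cycle protocols where cycle count is immaterial.  Metrics: percent
error per group is the relative difference of the means of the first
three per-cycle extrema (fewer with a warning if fewer cycles exist);
Pearson r over the full common time base; angle RMSE between simulated
trunk and measured angle in degrees.

## Known limitations

Single DOF; constant moment arms; group-identical activations (the PCSA
weighting only scales increments); lower-trapezius channels recorded but
excluded from both coupling groups; the IVD bushing is linear although
real discs are strongly nonlinear; coupling-stiffness insensitivity of
the recorded moment is ~1% per doubling of k_c (the settled angle shifts
by M/k_c and the force-length slope converts it), not exactly zero.
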