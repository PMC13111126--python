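# Methods

`caru` models calcium-induced calcium release (CICR) in a human
ventricular myocyte with a single aggregated calcium release unit of
tunable size: one population of L-type calcium channels (LCC) and one
population of ryanodine receptors (RyR2) gate stochastically inside an
otherwise deterministic whole-cell electrophysiology model.  The
channel count is the dial between regimes — a handful of channels
behaves like one dyadic microdomain, thousands recover the mean-field
whole-cell model.  This note records the model structure, the
numerical scheme, the calibration choices that were genuinely open,
and what the tests do and do not establish.

## Whole-cell scaffold

Membrane potential follows the standard capacitor balance
`C_m dV/dt = -I_ion + I_st` with the twelve-current decomposition of
the ten Tusscher–Panfilov human ventricular (epicardial) model.  All
sodium/potassium currents (I_Na, I_K1, I_to, I_Kr, I_Ks, I_NaK, I_pK,
I_bNa), their Hodgkin–Huxley gates, the sarcolemmal calcium handling
(NCX, plasma-membrane Ca pump, background Ca current) and the
intracellular Na/K bookkeeping are adopted unchanged from that
reference model and stay deterministic in both simulation modes.  Only
the L-type current and the SR release machinery are replaced by Markov
schemes.

Calcium cycles through three compartments (cytosol, SR, subsarcolemmal
subspace) with instantaneous single-buffer equilibria.  The model
evolves *total* calcium per compartment and recovers free calcium by
solving the binding quadratic each step; this is the stable reading of
the algebraic buffer relations and makes the volume-weighted total
`V_c Ca_i + V_sr Ca_SR + V_ss Ca_ss` exactly conserved when the
sarcolemmal fluxes are zeroed (a structural test in the suite).  The
saturating plasma-membrane pump uses the standard additive denominator
`G_pCa Ca/(K_pCa + Ca)`.

## RyR scheme

Four states — R (resting), O (open), RI (resting-inactivated), I
(inactivated).  Opening edges R→O and RI→I carry `k1·Ca_ss²` (CICR),
inactivation edges R→RI and O→I carry `k2·Ca_ss`, closures carry `k3`
and recoveries `k4`.  SR-load (luminal) control enters through

    kcasr(Ca_SR) = maxsr − (maxsr − minsr)/(1 + (EC/Ca_SR)²),

which falls from `maxsr = 2.5` (empty SR) to `minsr = 1.0` (overloaded
SR), with `k1 = φ·k1′/kcasr` and `k2 = k2′·kcasr·γ`.  The quotient in
k1 is deliberate: it is the reference model's convention and the only
orientation in which a fuller SR opens channels faster (luminal
facilitation).  A configuration switch (`kcasr_literal_product`)
allows the alternative product reading for sensitivity checks.  γ
defaults to 1 and is exposed only as a hook.

One printed rate was overridden: a recovery rate of `k4 = 1.5e-5 ms⁻¹`
implies a ~67 s recovery time constant from inactivation; under 1 Hz
pacing the available pool then collapses to a few percent within tens
of beats and SR release dies — incompatible with the healthy control
behavior this model is built to reproduce (we verified the collapse
numerically).  The default is therefore the reference model's
`k4 = 0.005 ms⁻¹`.

## LCC scheme

Seven states: C (resting closed), C′ (activated closed), O (open), If
and If2 (fast/deep voltage-inactivated), ICa (calcium-inactivated),
IfCa (doubly inactivated).  The per-edge rates are built from the
reference model's gate kinetics — for a gate with steady state
`x_inf(V)` and time constant `τ_x(V)` the forward rate is `x_inf/τ_x`
and the backward rate `(1−x_inf)/τ_x` — using the activation gate d,
the voltage-inactivation gates f and f2, and the subspace-calcium
gate fCass.  The topology is:

* an activation ladder C ⇌ C′ ⇌ O (d rates; the final opening is
  `φ·x7·d+`),
* the exact 2×2 product square O/If/ICa/IfCa of the fast voltage- and
  calcium-inactivation gates,
* the deep branch O ⇌ If2, and
* a closed-state inactivation edge C′ → If, because in the gate
  formulation f inactivates independently of activation; without it
  channels parked in C′ during the plateau stay artificially
  available.

The whole-cell current is Goldman–Hodgkin–Katz-shaped,
`I_CaL = O · G_CaL · 2F · (0.25·Ca_ss·e^z − Ca_o) · z/(e^z−1)` with
`z = 2(V−15)F/RT`, evaluated by series inside |z| < 1e−5 so the
removable singularity at V = 15 mV never divides by zero.  `O` is the
open *fraction* (count/N), so the deterministic whole-cell current is
independent of the channel count by construction; this normalization
is required for the large-N limit to converge to a well-defined
deterministic model.

This seven-state scheme is a reconstruction, not a transcription: it
reproduces the gate product in quasi-static structure but not exactly
(a 7-state chain cannot represent the full 16-state gate product).
Two consequences are documented rather than hidden: action potentials
are somewhat longer than the gate-based reference (~410 ms APD90 at
1 Hz vs ~300 ms), and the calcium transient is larger (~2.3 µM peak vs
~1 µM), mainly because the explicit 4-state RyR releases over tens of
milliseconds where the reference model's quasi-instantaneous open
fraction releases in a sharp early spike.

## Regulation dials

* `η` multiplies the two voltage-inactivation on-rates
  (`f− = η(1−f_inf)/τ_f`, `f2− = η(1−f2_inf)/τ_f2`) on every edge
  carrying them.  η = 0.5 slows inactivation (functional
  upregulation, more calcium entry); η = 1.5 accelerates it
  (downregulation).
* `φ` is a single phosphorylation level applied at its three targets
  at once: the LCC opening transition `t(C′→O) = φ·x7·d+`, the RyR
  opening rate `k1 = φ·k1′/kcasr`, and the SERCA affinity
  `K_up/φ` in `I_up = V_maxup/(1 + (K_up/φ)²/Ca_i²)`.

Both enter linearly on exactly their designated edges; the test suite
asserts the edge-by-edge linearity.

## Stochastic scheme

Channel populations advance by binomial tau-leaping at the shared step
Δt = 0.001 ms: for each occupied state the number of channels leaving
within Δt is `Binomial(n, 1 − e^(−k_tot Δt))` and is partitioned over
the outgoing transitions with probabilities `k_i/k_tot` (a joint
multinomial, realized by sequential conditional binomials).  Each
per-transition count is then marginally binomial with
`p_i = (1 − e^(−k_tot Δt))·k_i/k_tot`, which agrees with the
per-transition prescription `1 − e^(−k_i Δt)` to O(kΔt) — at the
largest rates in the model (≈5 ms⁻¹) the relative discrepancy is below
3·10⁻³, and the joint draw guarantees non-negative counts and exact
channel-number conservation, which per-edge independent draws do not.
Rates are frozen over each step at the step's initial (V, Ca).  An
event-exact Gillespie simulator (`ssa_exact`) serves as the
distributional oracle for the tau-leap scheme in the tests; it is
never used in production runs.

Deterministic mode integrates the master-equation occupancy ODE with
explicit Euler at the same Δt.  All continuous variables (V, gates,
concentrations, Na/K) use explicit Euler at the shared step; an
exponential (Rush–Larsen) gate update exists as an accuracy toggle in
the reference path.  Halving Δt changes the deterministic per-beat
release integral by < 0.5% (tested).

One seeded generator drives an entire simulation; trajectories are
bit-reproducible for a fixed (seed, configuration) pair.  Sweeps derive
per-condition seeds deterministically from the master seed.

## Pacing protocol and statistics

1 Hz rectangular stimulus (52 pA/pF for 1 ms, the reference model's
pacing pulse).  The full protocol is 1100 beats with the first 100
discarded (1000 analyzed); the scaled desk protocol (60 total / 10
discarded) is the default because full-scale sweeps need ~10⁹ steps
per condition.  Initial conditions are the reference model's published
1 Hz steady state; the discard block absorbs the adjustment to this
model's own limit cycle.

Per beat we record: the release integral S̄ = Δt·ΣI_rel (the Riemann
sum over one period), APD50/APD90 (threshold crossings of
`V_peak − f·(V_peak − V_diastolic)` with linear interpolation; the
upstroke reference is the threshold crossing itself, so a rectangular
pulse of width w has APD = w at every fraction; missing downstroke
crossings return NaN rather than raising, to tolerate
early-afterdepolarization morphologies), the peak free cytosolic
calcium and the diastolic SR load.

Dispersion is IQR/median of the per-beat S̄.  Bimodality is decided by
a two-component Gaussian mixture: bimodal iff the component means are
separated by more than twice the pooled within-component standard
deviation *and* the minor weight exceeds 0.1 — an explicit, seedable
stand-in for reading histograms by eye.  Histograms use the
Freedman–Diaconis rule.

The transition detector places the stochastic-to-deterministic
collapse at the grid value where the largest fold-reduction of
dispersion between successive powers of two *starts*, and flags no
transition when the largest fold is below a threshold (default 2.0;
pure 1/√N sampling noise gives √2 per doubling).  The threshold is a
config knob because "drastic reduction" is not quantified anywhere
authoritative.

## Calibration

The reconstruction left two scalars genuinely free: `x7` (the C′→O
opening scale) and `gain` (a multiplier on the whole-cell G_CaL).
They were fixed *before* any acceptance measurement by a
two-requirement rule: (1) the control model must converge robustly to
its deterministic limit at large N — specifically the mean S̄ of a
4096-channel run must sit within 2% of the deterministic value, since
robust control convergence is the defining property of the healthy
regime this model targets; (2) among settings satisfying (1), prefer
the smallest calcium transient (closest to the ~1 µM reference).
This gave x7 = 1, gain = 0.9.  Weaker gains (≤ 0.7) produce a
near-threshold CICR in which control beats randomly fail — the
phenotype this model reserves for the pathological dials — and were
rejected on that ground, not on any sweep outcome.

## Behavior of this parameterization

Numbers below are what the test suite and the acceptance script
compute on this code; they characterize the reconstruction, not the
biology.

* Control, deterministic, 1 Hz steady state: S̄ ≈ 2.27 mM per beat,
  APD90 ≈ 410 ms, peak Ca_i ≈ 2.2 µM, diastolic SR ≈ 3.7 mM.
* Control, stochastic: the relative dispersion of S̄ falls from
  ~90% at N_LCC = 16 to ~5% at N_LCC = 512 (r = 5), with
  fold-reductions of ~1.2–2.4 per doubling spread across the grid —
  a smooth collapse, largest at the 16–64 end.  A 4096-channel run
  matches the deterministic S̄ to ~1%.
* η = 0.5 (upregulation): second intra-beat release peak, S̄ above
  control, strongly prolonged AP.  η = 1.5: S̄ below control.
* φ = 2 (high phosphorylation): at N_LCC = 2048 the per-beat S̄
  distribution is clearly bimodal (beat-to-beat switching between
  normal and large release) while control at the same N is unimodal.
* φ = 0.5: the deterministic model settles into a stable period-1
  limit cycle with strongly reduced release; it does *not* develop
  calcium alternans at 1 Hz in this parameterization.  The
  release–load relation of the reconstructed scheme is evidently
  below the period-doubling threshold.

## Scope of the synthetic world

The aggregate unit is a mean-field abstraction: it has no spatial
structure, no diffusion between microdomains, no spark/wave
propagation, and a single shared subspace concentration.  The action
potential computed at small N is the model's local potential, not a
measurable cell AP.  Green tests therefore establish the internal
consistency of the hybrid scheme (conservation, distributional
correctness of the leaping, mean-field convergence, the direction and
location of the dispersion collapse) — they do not establish spatial
realism, absolute release magnitudes, or dwell-time statistics of
single channels, which the underlying schemes were never fit to.

## Numerical edge cases

* `buffered_free` solves the buffer quadratic with the numerically
  stable root; round-trips free→total→free to 1e−10.
* `I_up` at Ca_i = 0 returns 0 (the limit).
* `kcasr` rejects non-positive SR calcium.
* Tau-leap draws use the conditional-binomial decomposition, so a
  state can never emit more channels than it holds.
* A run that produces a non-finite V or negative total calcium stops
  and returns status 1 with the final state vector (sweeps record the
  failure and continue); the reference-path `step` raises instead.

## Known limitations

* The LCC scheme approximates, not reproduces, the reference gate
  product; AP duration and transient amplitude run high (numbers
  above).
* Explicit Euler at the fixed Δt = 0.001 ms is the prescribed hybrid
  scheme; no adaptive stepping.
* The γ hook and the literal-product kcasr reading exist but are
  untested against data; they are sensitivity switches only.
* The bimodality rule and the transition threshold are explicit
  operationalizations of judgments made visually in the source
  literature; both are exposed in configuration.
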