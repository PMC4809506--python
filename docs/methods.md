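# Methods

`bvrpop` studies beat-to-beat variability of ventricular repolarization
(BVR) with an experimentally-calibrated *population* of stochastic cardiac
action-potential (AP) models. This note documents the model, the numerical
choices, what the synthetic data emulate, and the limits of what the tests
demonstrate.

## Channel gating as reflected stochastic differential equations

Each of the four repolarizing currents that carry channel noise — I_Kr,
I_Ks, I_to1 and I_CaL — is a discrete-state Markov scheme. For a scheme
with occupancy-fraction vector X the package integrates the reflected SDE

    dX_t = A X_t dt + (1/sqrt(N)) E sqrt(D(X_t)) dW_t + K_t

where A is the transition-rate generator, the columns of E hold the +1/−1
stoichiometry of each transition, D(X) is diagonal with the per-transition
intensities d_k = rate_k(V) · X[from_k], N is the number of channels of that
type in the cell, and K_t is the boundary process that keeps every component
in [0, 1]. The Wiener increments have variance equal to the time step; the
boundary process is realised as the Euclidean projection of the post-step
vector onto the unit simplex, which enforces the bounds and conservation of
probability in a single operation. This construction is a direct diffusion
approximation of the underlying N-channel jump process: its drift equals the
deterministic gating model (A X = E d identically) and its noise covariance
(1/N) E D(X) Eᵀ matches the chemical-Langevin statistics, so the stationary
open-fraction distribution reproduces the binomial law p(1−p)/N. Fidelity is
verified against an exact Gillespie (SSA) oracle and the deterministic ODE
limit.

Numerical choices:

* **Step size.** dt = 0.01 ms for every stochastic AP run (no adaptivity
  inside stochastic trains — step-size control would bias the noise terms);
  0.02 ms for deterministic pacing. The dt-convergence test (halving dt
  leaves the stationary variance within Monte-Carlo error) validates the
  working step.
* **Rate floor.** Transition rates are clamped below at 1e-10 ms⁻¹ so
  square-root noise terms never see an exactly zero intensity.
* **Noise per reversible edge.** Inside the whole-cell kernel the two
  increments of a reversible transition pair are generated as one Gaussian
  of variance (d_f + d_b) dt. The pair shares one stoichiometry column up to
  sign, so this is *identical in distribution* to one increment per directed
  transition (the construction the generic engine uses literally).
* **Projection on demand.** The simplex projection is applied only on steps
  where a component actually leaves [0, 1]; interior points are fixed points
  of the projection, so this changes nothing.
* **Random numbers.** Each (model, repetition) pacing train draws its
  Gaussian increments from a splitmix64-seeded xorshift128+ stream with the
  Marsaglia polar transform, seeded through `numpy` `SeedSequence((seed,
  repetition))`. Identical seeds reproduce trains bit-for-bit, and results
  do not depend on any worker count because execution is sequential.
* **Rate tables.** Voltage-dependent quantities are tabulated on a 0.05-mV
  grid over [−120, 80] mV (nearest-neighbour lookup). The tables are built
  by evaluating the scheme objects themselves, so the kernel and the generic
  engine share identical rates.

## The reduced canine epicardial cell

The cell is a reduced epicardial ventricular myocyte built for
population-scale stochastic studies: fast sodium (Luo–Rudy m³h), a late
sodium current I_NaL (quasi-steady activation × slow inactivation gate,
τ_hL = 600 ms), inward-rectifier I_K1 (Luo–Rudy formulation), a linear
background current reversing at −40 mV, and the four Markov-schemed
repolarizing currents. Ionic concentrations are fixed (E_K ≈ −87.9 mV,
E_Na ≈ +70.5 mV, GHK driving term for calcium with Ca_i = 0.1 µM); there is
no calcium subsystem. Membrane capacitance 150 pF converts densities to
whole-cell currents for channel-number estimation.

The I_CaL steady-state activation is the double-sigmoid product

    ACT∞(V) = 1 / [(1 + e^{−(V−15.3356)/10.7558}) (1 + e^{−(V+12.8824)/2.1957})]

whose steep lower factor makes dome formation sensitive to the potential
reached after the notch — the coupling through which transient-outward
noise reaches the APD.

Design features that matter for the science:

* **I_to1 pedestal.** The inactivation gate keeps a non-inactivating
  pedestal of 3.5%, i.e. a small sustained (plateau) component of I_to1.
  Channel noise in this component acts directly on the plateau throughout
  repolarization, which is what makes I_to1 the dominant noise source in
  control conditions.
* **Plateau-sensitive I_Ks.** I_Ks activates slowly (τ ≈ 2 s at plateau
  potentials) with a right-shifted activation curve (V½ = +35 mV), so the
  amount of I_Ks recruited during an AP depends steeply on plateau height
  and AP duration. In control it contributes little; when I_Kr is blocked
  and the AP prolongs, I_Ks becomes the dominant repolarizing force — the
  classical repolarization reserve, and the mechanism behind the sign
  reversal of the N_to1–BVR relationship under I_Kr block (a larger I_to1
  lowers the plateau, recruits less I_Ks, and prolongs the AP).
* **I_NaL and the background current** give the range −60…−10 mV a small
  but definite net current. Without them, complete-I_Kr-block APs can hang
  near the background reversal, and high-g_to1/low-P_CaL corners of the
  population become stochastically bistable (all-or-none dome flicker).
  With them, such corners lose the dome *deterministically*, produce short
  APs, and are rejected by the APD calibration — mirroring how
  non-viable cells never enter an experimental sample.

Default maximal conductances (mS/µF): g_Na 12, g_NaL 0.0065, g_K1 0.5,
g_Kr 0.02, g_Ks 0.07, g_to1 0.26, P_CaL 1.9 (A/F per mV·mM), g_bg 0.010.
These give a control APD90 of ≈170 ms at 1 Hz pacing with a spike–notch–
dome epicardial morphology, a large prolongation under complete I_Kr block,
a small effect of I_Ks block, and strong shortening under 95% I_CaL
inhibition; the implied channel counts (next section) land in the
physiological thousands.

APD90 is measured from the instant of maximum upstroke velocity to the
first downward crossing of V_peak − 0.9 (V_peak − V_rest), linearly
interpolated between samples; a beat that never recrosses that level is
flagged as a repolarization failure, not an exception. Stimuli are 1-ms
rectangular pulses of −60 A/F (≈1.2× the baseline diastolic threshold; a
bisection utility `find_diastolic_threshold` is provided). Before every
stochastic train the model is prepaced deterministically until the
beat-to-beat APD change falls below 0.01 ms (up to 1000 beats).

## Population construction and calibration

Candidate models multiply the five conductances (g_Kr, g_Ks, g_to1, g_CaL,
g_K1) by Latin-hypercube-sampled factors in [0, 2]. Calibration is a pure
accept/reject conjunction of nine criteria: each scaling factor must lie
within mean ± 2.35 SD of the normalized experimental maximal-current
sample, and the deterministic APD under control and four blocks (complete
I_Kr, complete I_Ks, 95% I_CaL, complete I_Ks + 90% I_to1) plus the four
block-induced ΔAPD values must lie within mean ± 2.35 SD of the
experimental APD statistics (inclusive boundaries; APD is the mean of the
last five steady-state beats). Pharmacological block multiplies the
conductance by (1 − fraction) and leaves channel numbers unchanged — drugs
occlude channels, they do not remove them; a documented alternative would
rescale N as well.

The experimental statistics are synthetic (see below). The acceptance count
is emergent, never a target.

## Channel numbers

For I_Ks and I_CaL the single-channel current i is estimated by
nonstationary fluctuation analysis of clamp ensembles: across-sweep mean
I(t) and variance σ²(t) (baseline variance from the pre-pulse segment
subtracted), pooled into 20 equal-occupancy bins in I, then a
zero-intercept least-squares fit of σ² = i·I − I²/N. Channel numbers per
model follow as N_x = I_x/(i_x p_x), evaluated on the model's own simulated
clamp trace at the potential where the experimental i was quoted (+40 mV
for I_Ks, −15 mV for I_CaL, at the instant of peak |I|), with defaults
i_Ks = 0.15 pA and i_CaL = −0.6 pA. For I_to1 and I_Kr, where clean
ensembles cannot be measured, N is the scaled whole-cell maximal
conductance over a literature unitary conductance (γ_to1 = 19.722 pS,
γ_Kr = 2.5331 pS). N is rounded to the nearest integer because it enters
the SDE as a count. For the default cell this yields N_Kr ≈ 1.2·10³
(an order of magnitude below the rest), N_Ks ≈ 9·10³, N_to1 ≈ 2·10³,
N_CaL ≈ 6.5·10³ — all proportional to the conductance scaling factor, as
the fixed single-channel conductance demands.

## BVR quantification and attribution

Over the last 30 beats of each train (L generalizes the denominators to
2(L−1) for short test sequences):

    STV = Σ |APDₙ − APDₙ₋₁| / (2(L−1))        ran = max − min
    LTV = Σ |APDₙ + APDₙ₋₁ − 2·mean| / (2(L−1))   var = variance

STV and LTV are exactly the mean perpendicular and parallel distances of
the Poincaré points to the identity line (verified as an algebraic identity
in the tests). A zero LTV flags the STV/LTV ratio as missing, never
infinite. The standard protocol is an 80-beat train repeated 50 times;
the reduced desk scale used in the tests and the acceptance script is 40
beats × 10 repetitions × ≥8 models, with measures averaged over
repetitions before any across-model statistics (measures-then-average, not
beat pooling).

Contribution analysis reruns the trains with noise restricted to single
currents and reports each measure as a percentage of the all-currents case;
contributions are not additive. Attribution uses linear partial correlation
between each channel number and a BVR measure, controlling for the other
three channel numbers: Pearson correlation of the two residual vectors,
p-value from the t transform with n − 2 − 3 degrees of freedom,
significance at per-test p ≤ 0.05 (no multiple-testing correction by
default; a Benjamini–Hochberg switch exists, off by default). ΔBVR for a
drug condition is the per-model difference of repetition-averaged measures.

## Synthetic data: what it emulates, what it does not

No experimental recordings ship with the package; every input is generated
with known ground truth:

* **Clamp ensembles** — Gillespie sample paths of N channels (the oracle is
  deliberately independent of the SDE machinery under test), current
  i × (open count) plus Gaussian baseline noise, under holding/test-step
  protocols. Round trip: the fluctuation fit recovers i within 10% and N
  within 15% for N ∈ {500, 2000, 10000}.
* **Calibration statistics** — either configured directly (default SDs 10%
  of means) or computed from a chosen reference subset of candidate models,
  which turns calibration into a parameter-recovery experiment. In the
  pipeline the references are conductance-filter survivors with a viable
  control AP (APD in 120–320 ms), since experimental reference cells are
  viable by construction; the normalized maximal-current statistics use
  mean 1.0, SD 0.3.
* **APD sequences** — Gaussian AR(1) with configurable mean, SD and lag-1
  correlation; E[STV] = σ√(1−ρ)/√π in closed form.

What passing tests therefore show: the estimators and the stochastic
integrator are correct against their own generative laws and exact oracles,
and the *directional* physiology (I_to1 noise dominance in control, I_Ks
takeover under I_Kr block, the N_to1 correlation reversal) emerges on this
model family. What they cannot show: quantitative agreement with any real
canine dataset — the synthetic calibration statistics stand in for
unavailable experimental ranges, the reduced cell has no calcium cycling,
no transmural cell types, no drug-binding kinetics, and I_Na/I_NaL carry no
noise.

## Reduced problem sizes

The shipped tests and the acceptance script run the study at a reduced
scale chosen as the smallest population that still exercises every stage
meaningfully: 70 Latin-hypercube candidates, ≥8 calibrated models (10 are
carried into the stochastic stage), 10 repetitions of 40-beat trains
(last 30 analysed) in control and under complete I_Kr block, with
single-current noise subsets in control. Full-scale settings (1000
candidates, 50 × 80-beat trains) remain the configuration defaults.

## Known limitations

* With ~10 models and 10 repetitions, partial-correlation coefficients
  carry large sampling error (the t test at n = 10 with three controls has
  5 degrees of freedom); signs are reproducible, magnitudes are not.
* The all-or-none epicardial dome remains the stiffest feature of the
  model: deep in the high-g_to1/low-g_CaL corner, APs lose the dome. Such
  parameterizations are rejected by calibration, as non-repolarizing or
  short-AP models, rather than simulated.
* Fluctuation analysis assumes identical, independent channels and
  stationary gating kinetics across sweeps; series-resistance and
  capacitance artifacts are not modelled.
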