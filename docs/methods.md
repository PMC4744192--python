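# Methods

## Model

The measurement system is a dumbbell: two beads of summed radius *R* held
in traps of stiffness *k*₁, *k*₂ (series stiffness
*k*\_traps = *k*₁*k*₂/(*k*₁+*k*₂)), connected by a 2,260-bp dsDNA handle
(worm-like chain, persistence length *P* = 40 nm, contour length
*L* = 768.4 nm) in series with the protein under study.  The protein
contributes an unfolded polypeptide, modeled as a worm-like chain with
*P* = 0.6 nm and contour length *l* (the reaction coordinate, convertible
to residue number at 0.365 nm per amino acid), and a folded core of size
*h* along the pulling axis, modeled as a single freely-jointed segment so
that it can orient in the force field:

    H(F) = -kBT/F + h coth(F h / kBT).

At a trap separation *D* the force *F* of a state (l, h) solves

    D = x_m(F; l) + H(F; h) + x_DNA(F) + F/k_traps + R,

where the worm-like-chain extensions invert the Marko–Siggia force law.
Every term increases with *F*, so the root is unique; it is found by
bracketed Newton iteration to a residual below 1e-9 nm, vectorized over
states and trap separations.  The worm-like-chain stretching free energy
is used in the closed form

    G = (kBT L / 4P) (3t^2 - 2t^3)/(1 - t),  t = x/L,

which is the exact integral of the Marko–Siggia force.  The total energy
of a state at fixed *D* is

    G_i = G_m + V_i + G_DNA + F_i^2 / (2 k_traps)      [kBT],

i.e. the stretching entropies of polypeptide and handle, the zero-force
free energy V_i of the landscape, and the potential energy of the beads.
Populations follow the Boltzmann distribution over the stable states;
transition rates follow Kramers' picture with a single shared attempt
frequency A:

    k(i -> j) = A exp(-(G_ts - G_i)),

where G_ts is the total energy of the transition state between i and j.
Detailed balance holds exactly by construction.  The orientation entropy
of the folded core is not part of G (only its extension enters the force
balance); energies are therefore defined relative to states of the same
tether, which is all the analysis ever uses.

A uniform shift of all transition-state V's is exactly degenerate with a
rescaling of A given populations and rates, so A is an input, fixed at
1e6 s⁻¹ by default, never fitted.  Barrier heights are reported relative
to this convention.

Units everywhere: nm, pN, kBT (with kB·T computed from the configured
temperature; 296 K gives 4.087 pN·nm = 0.59 kcal/mol), seconds.

## Landscape fixtures and calibration

The wild-type fixture has four stable states — state 2 (linker domain
unfolded), state 3 (C-terminal domain unfolded, half-zippered), state 4
(middle domain unfolded) and state 5 (fully unzipped v-SNARE on a folded
t-SNARE three-helix bundle) — with zero-force energies 0, 22, 35 and
60 kBT (domain energies CTD 22, MD 13, NTD 25 kBT).  CTD and NTD folding
are downhill at zero force (their transition-state V equals the unfolded
member's V); the MD transition state sits 5 kBT above the MD-unfolded
state, close to the ionic-layer border of the middle domain.

The contour lengths, core sizes and the default trap stiffness are *not*
structure-derived: they were calibrated numerically (results frozen as
constants in `fixtures.py`) so that under the default
tether configuration the pair equilibrium forces and extension changes
reproduce the measured values — CTD 16.5 pN with a 6.7-nm extension
change, MD and NTD 17.2 pN with a 3.6-nm MD change.  A trap stiffness of
k1 = k2 = 0.3 pN/nm cannot satisfy the CTD force and extension change
simultaneously at ΔV = 22 kBT (the extension change comes out 7.1 nm);
k1 = k2 = 0.5 pN/nm — well inside the normal operating range of a
dual-trap instrument — satisfies all of them, and is the packaged
default.  h(l) ships as the monotone piecewise-linear table through the
calibrated state knots, falling to zero once the t-SNARE is unfolded;
transition states interpolate the same table.

Mutant fixtures shift domain energies relative to wild type with the
geometry held fixed: V39A/V42A (NTD −3 kBT), L70A (CTD −10), F77A
(CTD −12), M71A/I192A (CTD −13), T251I (CTD +5); L60A/L63A remove the
independent MD intermediate (CTD_MD folds as one 35-kBT unit) and M46A
merges MD with NTD the same way.  `wt_pull` appends the irreversibly
unfolding t-SNARE (state 6) behind a 31-kBT barrier placed so that the
final rip falls at 20–30 pN when pulling at 10 nm/s; it is used with the
absorbing-state option of the simulator, which models the loss of SNAP-25
after t-SNARE unfolding (no reassembly on relaxation).

## Synthetic instrument

Constant-trap-separation traces are continuous-time Markov (Gillespie)
hopping among the stable states with the model's rates at that *D*,
emitted at 20 kHz with white Gaussian noise (default SD 2.0 nm per raw
sample, i.e. 1.0 nm at an effective 5 kHz analysis bandwidth) and
boxcar-decimated to 10 kHz, mirroring an online filter.  The emitted
force co-fluctuates with extension as required at fixed trap separation
(δF = −k_traps·δx).  Ramped FECs follow the current state's elastic
branch while *D* moves at constant speed (default 10 nm/s), with
transitions generated by thinning against a windowed local rate majorant;
near-equilibrium flickering and hysteretic rips emerge from the rates
alone.  Rare ligand-bound states are injected as a Poisson process that
freezes the chain in a target state with a shifted extension for
exponentially distributed dwells; overlapping injections merge.

What the generator does **not** emulate: bead–handle Langevin dynamics
and hydrodynamics (noise is white, whereas real filtered traces carry
colored noise from bead relaxation), instrument drift, calibration
errors, tether rupture, and the residual hopping observed within bound
states in real data.  Passing tests therefore demonstrate correctness of
the inference given the model's statistical structure, not robustness to
instrument systematics.

## Trajectory idealization

Traces are mean-filtered to 5 kHz (0.2 ms boxcar) before analysis, as in
standard practice.  The number of states is counted by fitting the
extension histogram with Gaussian mixtures (BIC over 1–6 components;
components closer than two pooled SDs are merged as unidentifiable).  The
HMM has Gaussian emissions and is maximized by expectation–maximization
(Baum–Welch); the likelihood is non-decreasing per iteration and
convergence is declared at 1e-8 per sample.  Idealized paths come from
the Viterbi algorithm (ties broken toward the lower state index);
populations are occupancy fractions, rates are transition counts over
time in state, lifetimes are mean uncensored dwells.

State identity across trap separations is anchored in contour-length
space: each mixture component's mean extension is inverted through the
tether model to a contour length (a *D*-independent coordinate), the
pooled values are clustered by a greedy merge (states are several nm
apart on *l*; component noise is sub-nm), and each trace's HMM is
initialized at the model-predicted extensions of the consensus states.
Slots with occupancy below 0.1% in a trace are excluded from that trace's
HMM and flagged unvisited rather than fitted to nothing.

Three guards keep biased observables out of the landscape fit, all
exposed as parameters of `assemble_observations`:

* state forces and extension changes require ≥ 8% occupancy — the fitted
  emission mean of a nearly-empty state is dragged toward its heavy
  neighbour by samples that straddle a transition within one filter
  window, entering the fit as a precisely wrong number;
* extension changes use medians of the Viterbi-assigned samples, which
  resist the same one-sided contamination;
* rates require ≥ 5 transitions and an observed mean dwell of ≥ 8
  filtered samples (shorter dwells are systematically undercounted at
  finite bandwidth — the missed-event problem).

The rare-bound-state detector flags contiguous intervals whose extension
is more than 4 SDs from every baseline state for at least 30 ms, and
reports the occurrence rate and mean dwell; the baseline model should be
fitted on a ligand-free record.

## Landscape fitting

The fit minimizes the weighted sum of squared residuals of predicted
versus observed state forces, populations, log rates (their dynamic range
spans decades) and adjacent-state extension changes, across all trap
separations simultaneously.  Parameters: the first state's contour
length, the contour gaps, the cumulative V's (gauge: V = 0 for the
most-folded observed state), the fractional transition-state positions
within each gap, and the barrier offsets above the higher-V member of
each pair; h is tied to l through the packaged table.  The topology
(number and order of states) is declared by the initial landscape and
never searched.  Optimization is bounded least squares
(`scipy.optimize.least_squares`) with 20 seeded multi-starts around a
crude data-derived initial landscape (contour gaps from extension changes
via the polypeptide's fractional extension; V's from F·Δx at the
occupancy crossover).  Parameter SDs come from the Gauss–Newton
covariance scaled by the reduced chi-square; a parametric bootstrap
(perturb observations by their uncertainties, refit from the optimum) is
available via `n_bootstrap` for a sampling-based alternative.

Derived quantities: domain energies are V-differences across adjacent
stable pairs (named CTD/MD/NTD for the four-state topology), the MD
barrier is the transition-state V above the MD-unfolded state, the total
zippering energy adds a fixed 8-kBT linker-domain term (characterized
independently; not refit), and equilibrium forces are found by bisection
over *D* for equal total energies, with the combined MD/NTD value the
population-weighted mean of the two pair equilibria.

## Recovery protocol and problem sizes

The end-to-end validation (also run by `scripts/acceptance.py`) simulates
ten 20-s wild-type traces at 10 kHz, with trap separations spaced
uniformly in *D* between the separations whose mean forces are 14.5 and
19.5 pN.  Uniform *D* spacing matters: the population-weighted mean force
is nearly flat across the transition region (population exchange
compensates tether stiffening), so spacing traces uniformly in mean force
would leave the informative region undersampled.  The full run — about
2×10⁶ analyzed samples, HMM idealization, and the multi-start fit —
recovers all domain energies within a fraction of their experimental
SDs and completes in a few minutes on one CPU.

## Numerical choices and edge cases

* Worm-like-chain inversion: safeguarded Newton from an analytic upper
  bound on the fractional extension; the force law is convex and
  increasing so the iteration is monotone.  Relative tolerance 1e-12.
* Freely-jointed-chain extension below F·h/kBT = 1e-3 uses a three-term
  Taylor series to avoid catastrophic cancellation at F → 0.
* The force balance refuses D < R (slack tether returns F = 0 at D = R)
  and reports non-convergence if no root exists below 200 pN.
* Equilibrium-force bisection scans 60 points over a default *D* window
  wide enough for ~40 pN of bead displacement before root-polishing;
  degenerate or non-adjacent pairs are rejected.
* FEC rip detection: steps of the 1-ms-smoothed extension exceeding 5
  robust step SDs within 2 ms.  The threshold is deliberately above the
  3-SD convention because detection runs at full bandwidth where a 3-SD
  cut would fire on noise hundreds of times per ramp; both parameters are
  exposed.
* Flicker equilibria correct the folded-branch mean force to the
  equal-occupancy point via kBT·ln(p_f/p_u)/Δx, making the estimate
  insensitive to window placement; bimodality requires Ashman's D ≥ 2.
* Skip (non-adjacent) transitions are disabled by default.  The optional
  `include_skip` rate is the steady-state through-flux across the
  intervening states.  Note that observed non-sequential rates in
  idealized data are far smaller than this flux whenever the intermediate
  dwells are resolved — the sequentiality test asserts exactly that
  observable (non-sequential transition counts < 1% of sequential ones).

## Known limitations

* The Kramers prefactor is conventional; barrier heights shift by ln(A'/A)
  under a different choice.  Only energy *differences* between stable
  states are prefactor-independent.
* Rates measured at 5 kHz on states with ~1 ms dwells carry a residual
  ~10% missed-event underestimate; the dwell guard removes the badly
  biased observations but not this floor.  Populations are unaffected.
* The fixture geometry (l, h) reproduces the measured mechanical
  observables but is not a structural model; residue-number annotations
  via 0.365 nm/aa are approximate.
* The fit assumes the declared topology; it will not discover a missing
  or merged intermediate on its own (compare fixtures with
  `compare_landscapes`, which flags incomparable topologies).
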