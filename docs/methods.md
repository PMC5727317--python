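# Model and methods

## The system

Mixing the cyanobacterial clock proteins KaiA, KaiB and KaiC with ATP
reconstitutes a circadian rhythm in vitro: the phosphorylation level of
KaiC hexamers oscillates with a period near 24 h.  Each KaiC subunit has
an N-terminal CI domain carrying a slow ATPase and a C-terminal CII
domain carrying the phosphorylation sites; the hexamer switches between
two collective conformations — a ground state (gs) that binds KaiA on
the CII ring and phosphorylates, and a competent state (cs) that binds
KaiB on the CI ring and dephosphorylates.  Experimentally, the ATPase
turnover measured on KaiC alone correlates with the rhythm frequency of
the full mixture, suggesting the slow CI hydrolysis cycle paces the
clock.  `kaisim` implements a multifold-feedback model of this system:
reactions modulate the hexamer structure, the structure modulates the
reactions, and stochastic ATP hydrolysis perturbs the structure.

## State of one hexamer

Each of N hexamers carries

* a probability vector over 29 binding states: the CII complex C6A2
  (one KaiA dimer on the CII ring) and the CI complexes C6BiA2j with
  0 <= j <= i <= 6 (i KaiB monomers, j of them holding a KaiA dimer;
  (0,0) is free C6);
* a continuous phosphorylation level D in ~[0, 1] coarse-graining the
  12 CII sites;
* a structural order parameter X in (0, 1) (gs ~ 1, cs ~ 0);
* six boolean ADP flags, one per CI domain.

The N-body distribution is factorized into per-hexamer one-body
distributions (a Hartree-like mean-field closure); hexamers interact
only through the shared free KaiA and KaiB pools, obtained algebraically
from total-amount conservation

    A = A_T - (2/V) * sum_k [p_CA(k) + sum_ij j p_ij(k)],
    B = B_T - (1/V) * sum_k  sum_ij i p_ij(k),

where A counts KaiA monomers (each dimer = 2) and V is the system
volume.  Units follow V = 1, k_B T = 1, time in hours.

## Dynamics

**Binding kinetics.**  The per-hexamer master equation uses mass-action
rates: C6 <-> C6A2 at h_A A^2 / f_A (KaiA binds as a dimer); KaiB
binding (6-i) h_B B and unbinding (i-j) f_B (only KaiA-free KaiB can
leave); KaiA on bound KaiB at (i-j) h_BA A^2 and j f_BA.  The rates on
KaiC itself are structure-modulated,

    h_A = h_A0 X,   f_A = f_A0 (1-X),   h_B = h_B0 (1-X),   f_B = f_B0 X,

so the gs state recruits KaiA and the cs state recruits KaiB, while
KaiA exchange on KaiB is structure-independent.

**Phosphorylation.**  dD/dt = k_p p_CA - k_dp (1 - p_CA) - g'(D) with
the quartic soft-spin confinement g(D) = a D (D-1/2)^2 (D-1).  With the
default rates (k_p = k_dp = a/4) the confined fixed points sit exactly
at D = 0 (no KaiA drive) and D = 1 (full drive).

**Structure.**  The conformational transition is much faster than any
reaction, so X is the quasi-equilibrium mean of a rigidly coupled
six-spin ring in the instantaneous field

    h = c0 - c1 D + c2 pA - c3 pB - q,      X = (tanh(beta h) + 1)/2,

where pA = p_CA, pB = sum_i tanh(i/n_B) sum_j p_ij saturates with the
KaiB load, and q is the hydrolysis perturbation below.  The exact
64-configuration enumeration of the finite-coupling ring is kept as a
test oracle for this strong-coupling limit.

**ATP hydrolysis.**  Each ADP-free CI domain releases Pi with constant
hazard f0; the event leaves ADP bound, contributing q0 to q (so
q = q0 * n_bound, up to 6 q0) and making the subunit refractory.  Bound
ADP is released with the structure-dependent hazard

    1 / delta(X),     delta(X) = delta0 (gamma - X),

i.e. the mean ADP residence time is delta0(gamma - X): short in the gs
state, long in the cs state.  Under a frozen structure the release
process is a renewal process with rate 1/(1/f0 + delta) per subunit and
hypoexponential inter-event intervals; both properties are verified
against the stepping code.

We deliberately model the residence time through an instantaneous
hazard rather than by fixing a deterministic lifetime at the moment of
release.  The two readings share the same mean, but they differ
dynamically: with lifetimes frozen at release, ADP loads acquired while
a hexamer is in the cs state never re-shorten when the structure
recovers, the deep cs state becomes effectively absorbing, and the
ensemble rhythm at the reference parameters degrades to a marginal,
noise-sustained oscillation.  With the instantaneous hazard the ADP
pool tracks the structure, the reference parameter set sits well inside
the oscillatory region, and the model reproduces the expected
phenomenology (onset in q0, f0 and KaiA concentration; weakened
synchronization at low f0).  The hazard form is therefore the package's
definition of the lifetime law.

## Reference parameters

Defaults (per hour, per k_B T, V = 1): N = 1000, A_T/C6T = 2,
B_T/C6T = 20 with C6T = N/V; h_A0 = 1.6e-5, h_B0 = 7.2e-6,
h_BA = 1.0e-6, f_A0 = 0.8, f_B0 = 0.32, f_BA = 0.2; k_p = k_dp = 0.4,
a = 1.6; c0 = 10, c1 = 6, c2 = 0, c3 = 3, beta = 1, n_B = 1; f0 = 2.4,
q0 = 0.8, delta0 = 2.5 h, gamma = 1.5.  The c2 (KaiA-binding) term is
implemented and tested but disabled by default.  KaiA binding is fast
(h_A0 A_T^2 ~ 64/h), KaiB binding slow (h_B0 B_T ~ 0.14/h per site),
which staggers the two sequestration routes across the cycle.

`rescale_ensemble(params, N_new)` changes the ensemble size with the
volume scaled along, so all concentrations — and therefore the
per-hexamer dynamics — are unchanged; only the 1/sqrt(N) noise of
ensemble averages grows.  Desk-scale analyses in the tests and the
acceptance script use N = 200.

## Numerical scheme

One hybrid step of size dt applies, in fixed order: (1) free pools from
conservation; (2) explicit-Euler update of each 29-state distribution,
negatives clipped and the vector renormalized (corrections above 1e-6
are logged; above 1e-3 the run aborts as a step-size failure); (3)
Euler update of D; (4) Bernoulli draws with p = 1 - exp(-rate dt) for
Pi release and ADP release, one uniform per subunit per step so random
streams stay aligned; (5) algebraic re-evaluation of X.  Structure is
updated last so the next step's rates see the current conformation.

The default step is dt = 0.002 h (fastest rate h_A0 A_T^2 ~ 64/h gives
dt*rate ~ 0.13); sweep-scale analyses use dt = 0.005 h, validated by a
step-halving oracle on the deterministic skeleton (f0 = 0) and by the
renewal-rate checks (discretization bias < 1%).  Accuracy is certified
by these oracles rather than by scheme order.  The compiled kernel and
a plain numpy reference step are verified to agree bit-for-bit on
deterministic paths and statistically on stochastic ones.  Runs are
bit-reproducible for a given seed: the initial conditions use one
numpy Generator stream and the kernel a separately seeded stream
consumed in fixed hexamer order.

**Initial conditions.**  All hexamers start as free C6 with no ADP
bound; D is i.i.d. uniform on [0, 1] so ensemble coherence must emerge
through KaiA sequestration rather than being imposed; X starts on the
quasi-equilibrium map.  Analyses discard a transient (500 h at full
scale, 200 h in shorter desk-scale runs).

## Observables

* **Amplitude** Delta-Dbar: 97.5th minus 2.5th percentile of the
  post-transient ensemble mean D; percentiles rather than extremes keep
  the estimate robust to finite-N noise.  A run counts as oscillating
  when Delta-Dbar > 0.1 (about a sixth of a full-swing rhythm).
* **Period**: the ensemble D series is mean-removed, Hann-windowed and
  Fourier transformed; the peak bin (zero excluded) is refined by
  quadratic interpolation of log power; tau = 1/f_p.  A peak below 5x
  the median spectral power is flagged as "no peak".
* **ATPase activity**: Pi-release events per CI subunit per 24 h in the
  partner-free condition A_T = B_T = 0, the condition in which the
  hydrolysis turnover of KaiC alone is assayed.  At the defaults the
  partner-free ensemble rests in the gs state and the renewal rate
  gives ~ 24/(1/f0 + delta0(gamma-1)) ~ 14 ADP per CI per day.
* **Sweeps**: amplitude/period vs q0, delta0, f0, A_T, B_T with
  independent seeds per point (mean +/- SE); the KaiA onset threshold is
  the smallest A_T/C6T whose amplitude exceeds half the reference
  amplitude at A_T/C6T = 2, B_T/C6T = 20; the activity-frequency slope
  is the OLS slope of f_p (day^-1, oscillatory condition) on activity
  (ADP/CI/day, partner-free condition) across f0, with non-oscillating
  points dropped; the compensation surrogate compares the spread of tau
  over f0 with delta0 fixed versus with f0*delta0 held constant,
  emulating joint thermal acceleration of hydrolysis and ADP release.

## What the simulations do and do not emulate

The generator produces the in-vitro reconstituted system under the
model's idealizations: well-stirred shared pools, factorized binding
statistics, one collective structural coordinate, one coarse-grained
phosphorylation level.  It does not distinguish the two phosphorylation
sites (Ser431/Thr432) or the CI/CII conformations separately, does not
model monomer shuffling or nucleotide exchange beyond the binary
ADP-bound flag, and treats binding deterministically per hexamer (no
molecular binding noise).  Passing tests therefore demonstrate the
internal consistency of this model and its reported collective
behavior, not quantitative agreement with any particular experimental
dataset.

Finite-size caveat: desk-scale runs (N = 200, 600-800 h) carry ~2x the
ensemble noise of full-scale runs; the measured period is mildly
noise-sensitive, so the activity-frequency slope at desk scale comes
out somewhat steeper than at full scale.  Thresholds and orderings are
stable under halving N and t_end; degradation shows up as wider seed
scatter, which the sweep tables report rather than hide.

## Known limitations

* Explicit Euler with clipping is first-order; accuracy rests on the
  convergence and stationary-distribution oracles, not scheme order.
* The amplitude definition (percentile range) differs from peak-to-
  trough readings by the noise floor (~0.02-0.03 at N = 200); classify
  runs with the documented 0.1 threshold, not by eye.
* At A_T/C6T >~ 3.5 the fast KaiA binding makes dt = 0.005 h too
  coarse; the normalization guard aborts such runs instead of silently
  degrading (use a smaller dt there).
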