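# Methods

This note documents the models, algorithms, and numerical choices behind
`hremkit`, and what the package's validation does and does not establish.

## 1. Sampling model

The object of study is replica exchange over a ladder of scaled Hamiltonians,
not molecular kinetics.  Each model system is a one-dimensional collective
coordinate (a torsional angle on the circle `[−π, π)` or a bounded distance)
with an analytic potential `U(x)` in kcal/mol.  "Dynamics" are a local-move
Metropolis random walk targeting `exp(−β s U)`, with β = 1/RT,
R = 1.987204×10⁻³ kcal/(mol·K), and T = 300 K by default.  Proposals are
uniform in `x ± δ`; periodic coordinates wrap, bounded coordinates treat the
domain edge as a hard wall (out-of-domain proposals are rejected, which
preserves detailed balance under the symmetric proposal).  Because only
state-space connectivity and stationary weights matter for the questions the
package addresses, this chain is an adequate stand-in for an MD integrator
provided moves are *local*: the step must be small against the basin width so
that barrier crossings remain rare events.  Default steps: 10° for the
low-barrier torsion, 5° for the high-barrier torsions (a smaller step keeps
the crossing rate over the ≈5–8 kcal/mol fixture barriers in the rare-event
regime at the budgets used here), 0.15 Å for the distance coordinate.

Angles are radians internally and degrees at every I/O boundary.

## 2. Model systems (frozen fixture constants)

* **phenyl** — `U(θ) = (B/2)(1 − cos 2θ) + (Δ/2)(1 − cos θ)`, B = 0.9,
  Δ = 0.2 kcal/mol.  Wells at 0 ("symmetric") and π ("twisted"), well offset
  0.2 kcal/mol, barrier ≈1.0 kcal/mol.  Note that the *basin free-energy*
  gap from quadrature is 0.166 kcal/mol, not 0.2: the twisted well is
  slightly wider (lower curvature), contributing an entropic ≈0.03 kcal/mol.
  Recovery tests therefore compare against the quadrature value.
* **naphthyl_t1** — two-fold torsion with barrier 5.0 kcal/mol and wells
  split by 0.5 kcal/mol.
* **naphthyl_t2** — three-fold-dominated torsion with the global well near
  −60°, a secondary well displaced by +120° and ≈1 kcal/mol shallower, a
  strongly penalized third well at 180°, and a barrier of ≈8 kcal/mol above
  the global minimum.  The barrier height is a design choice: the modelled
  regime is "long-lived metastable states that plain sampling cannot leave at
  the allotted budget", and 8 kcal/mol puts the Kramers-estimate crossing
  count for a 4×10⁵-step chain near 0.02, so the zero-crossing behaviour of
  the plain protocols is a property of the system, not of a lucky seed.
* **two_pose** — quartic distance double well
  `U(r) = k((r−c)² − d²)² + λ(c − r)` on [9, 18] Å with c = 13 Å, d = 1.5 Å,
  k = 0.8 kcal/mol/Å⁴ (wells near 11.5 and 14.5 Å; barrier ≈4.8 kcal/mol
  above the major well).  The offset λ is solved by bisection so that the
  quadrature population of r < 13 Å equals the requested minor-pose
  probability (default 7%) to within 10⁻⁴.  k was fixed a priori by a Kramers
  estimate so that one 2×10⁵-step chain crosses into the minor pose about
  once on average — the "rare but observable in a replicate swarm" regime.

Basin partitions deliberately exclude the barrier regions (e.g. the minor
pose is r < 12 Å, the major pose r > 13.5 Å), so transition counting is not
contaminated by barrier-top recrossings.  Empirical basin fractions are
estimated over labelled samples only, and are therefore compared against
quadrature populations renormalized over the labelled region.

## 3. The Gaussian energy bath

Mean potential energy and its variance are extensive, so a molecule with
hundreds of scaled degrees of freedom has much lower exchange acceptance
than a bare 1-dof coordinate, and it is exactly this acceptance structure the
ladder machinery operates on.  Each system therefore carries a Gaussian
energy model of the remaining scaled dofs: N dofs with per-dof variance σ₀²
(phenyl: N = 50, σ₀² = 0.32; the 12-replica systems: N = 128, σ₀² = 0.5,
i.e. total σ of 4 and 8 kcal/mol).  Sampling `exp(−β s U)` against a
Gaussian density of states gives the exact conditional
`U | s ~ N(μ − β s σ², σ²)`, and the engine draws a *fresh* bath energy from
this conditional at every exchange attempt (an idealized, infinitely fast
bath relaxation).

This construction is exact, not an approximation to be excused: the noise it
adds to the exchange exponent Δ has density `f` with `f(−z) = e^{−z} f(z)`,
from which `E[min(1, e^{−t−Z})] = e^{−t} E[min(1, e^{t−Z})]` follows by a
change of variables — the marginal exchange kernel on the coordinate still
satisfies detailed balance exactly.  The coordinate's target-state law is
untouched (the bath is independent of the coordinate chain), while per-pair
acceptances acquire realistic magnitudes and the increasing-with-k profile
characteristic of a constant-width energy distribution.  The validation
suite tests Boltzmann correctness of the target state *with the bath on*.

For a purely harmonic bath (energy width ∝ 1/s) the geometric ladder is
already balanced; the constant-width Gaussian model is the minimal stand-in
for the anharmonic behaviour that makes acceptance equalization a nontrivial
problem in the first place.

## 4. Ladder construction and the adaptive update

The geometric protocol is `s_k = s_min^((k−1)/(n−1))`.  The adaptive update
measures per-pair acceptances `P_acc(k)` over a window of exchange sweeps and
corrects the gaps multiplicatively,

    g_k = Δs_k · [1 + c·σ·(P_acc(k) − ⟨P_acc⟩)],   Δs′ = g · (1 − s_min)/Σg ,

with σ the population standard deviation of the `P_acc(k)` over the n−1
pairs (the same convention is used for the reported spread `δP_acc`).  The
renormalization enforces `Σ Δs = 1 − s_min` exactly (to 10⁻¹²) at every
iteration; the last rung is pinned to `s_min` after the cumulative sum to
avoid rounding drift.  The sign convention — above-mean acceptance widens
the gap — is the only self-consistent one, since a wider scaling gap reduces
the energy-distribution overlap and hence the acceptance.  A balanced ladder
(σ = 0) is an exact fixed point.  If any corrected gap is non-positive the
update raises an instability, and the engine resets to the geometric ladder
and halves the gain c (backoff factor 0.5).  Because the correction is
proportional to σ times a deviation that itself scales with σ, convergence
near the fixed point is slow (σ ~ 1/iterations); the fixed-point test
iterates a deterministic surrogate (the bath's closed-form acceptance
`P = erfc(β Δs σ_tot / 2)`) until the spread falls below 10⁻³.

Defaults: gain c = 2, ten iteration windows occupying the first 10% of the
run, after which the ladder is frozen and production statistics are
collected.  δP_acc comparisons between adaptive and geometric ladders are
always made over equal post-adaptation attempt counts.

## 5. Engine conventions

Exchanges are attempted between contiguous pairs only, sweeping even pairs
and odd pairs on alternating sweeps, every `attempt_interval` Metropolis
steps (default 25 in the API; the benchmark protocols use 10 — one sweep per
10 steps — as the package's dictionary for "high exchange attempt
frequency").  The exchange exponent is `Δ = β (s_k − s_{k+1}) (U_b − U_a)`
on unscaled energies; what is exchanged is the pair of scaling factors, so a
replica (walker) is a trajectory wandering through the ladder.  Node-indexed
storage makes this a swap of configurations and walker ids between node
slots; a test checks the equivalence of the scaling-swap and
configuration-swap conventions against an independently coded pure-Python
reference engine.  The walker-by-node record is asserted to be a permutation
at every sweep (replica conservation).  An `n = 1` ladder is legal and
reduces the engine exactly to the plain chain.

All randomness flows from one master seed through `numpy.SeedSequence`; the
jitted kernels seed their internal generator per block, so every run is
bit-reproducible given (arguments, seed).

## 6. Diagnostics

* **Flux**: a walker is labelled "up" when its last extreme contact was the
  target node and "down" when it was the most-scaled node (relabelled on
  arrival *before* the visit is counted, so f_u is pinned to 1 and 0 at the
  ends); `f_u(k) = z_u(k)/(z_u(k)+z_d(k))`.  The ideality reference is the
  endpoint-pinned line `(n−1−k)/(n−1)` (0-based k), which is the exact
  labelled-process profile of an unbiased walk; `Δf_up` is the mean absolute
  deviation from it over nodes with labelled visits.
* **First-passage flux**: the node-occupancy chain is fitted as a
  birth-death chain from transition counts and `f_u(k)` is computed as the
  splitting probability of reaching the target node before the most-scaled
  node (exact tridiagonal solve) — justified by the reversibility of the
  occupancy chain and validated against direct counting to 0.05 per node on
  10⁶-step synthetic walks.
* **RTT**: a round trip is the milestone sequence node 1 → node n → node 1;
  partial trips at the record end are discarded; the mean is over all
  completed trips of all walkers and is reported as missing (never 0) when
  no trip completed.  Validated to 5% against the exact linear-solve mean
  first-passage time on a synthetic walk.
* **Residence variance**: `δτ² = (1/(m n)) Σ_i Σ_k (n τ_i(k) − 1)²` — the
  per-cell mean-square deviation of the normalized residence fractions,
  dimensionless, 0 at ideal uniform residence (the normalization by `m·n` is
  a documented choice).  It is exactly 0 on the deterministic
  cyclic-occupancy fixture and exactly 1 for frozen replicas at n = 2, and
  is invariant under relabelling of replicas and nodes.

## 7. PMF and basin free energies

`V_PMF = −RT ln(P/max P)` over histograms (default 72 bins over
[−180°, 180°) for torsions, 0.25 Å bins for distances); empty bins are
masked, never ±∞, and the minimum over unmasked bins is exactly 0.  Basin
ΔF values are computed from *integrated basin populations*
(`ΔF = −RT ln(p_b/p_a)`), the physically meaningful comparison for conformer
Boltzmann weights, not from PMF minima.  Uncertainties use block averaging
with 10 contiguous blocks; blocks missing a basin are dropped from the SE
(and the SE is undefined if fewer than two blocks remain — estimates from
trajectories that never visit a basin are reported as missing, not as 0).

## 8. Benchmark protocols and study conditions

The three-protocol comparison grants every protocol the same step currency:
with n replicas of S steps each, the single chain gets n·S steps and m
replicates get n·S/m steps each ("total" mode); in "target" mode the plain
protocols get only the HREM target-state budget S — the honest comparison
when only target-state samples are analyzed.  The validation suite uses, per
system: phenyl — n = 8, s_min = 0.1, 10⁶ exchange sweeps at one sweep per 10
steps for the Boltzmann-recovery check and 5×10⁴ sweeps for the equalization
check; naphthyl_t2 and two_pose — n = 12, s_min = 0.1, with 4×10⁵ and 2×10⁵
steps per protocol respectively.  The two_pose "short exploratory chain" is
4×10³ steps started at the major-pose minimum: about 3% of the expected
first-passage time to the minor pose, so it characteristically reports zero
minor-pose samples where the 12-replicate pool (crossing ≈12 times in
aggregate) and HREM both recover the 7% population.  These sizes were chosen
to reproduce the separation of regimes on commodity hardware in minutes and
are stated here as the package's study conditions.

## 9. What the tests do and do not show

The synthetic fixtures emulate barrier topology, Boltzmann weights, and the
acceptance structure of extensive systems; they do not emulate inertial
dynamics, solvent friction, multidimensional transition pathways, or the
coupling between a hot solute zone and cold surroundings in solute-tempering
setups (the entire model Hamiltonian is scaled).  Quantities tied to real
time (EAF in ps⁻¹, RTT in ns) appear here in sweep units; conclusions about
*relative* protocol efficiency transfer, absolute rates do not.  Printed
metric values from atomistic studies of the corresponding real systems are
therefore mirrored qualitatively (directions of effect, regime contrasts),
never asserted numerically.

## 10. Known limitations

* The adaptive update needs every pair attempted within a window; very small
  windows on large ladders raise an error rather than guessing.
* The first-passage flux estimator requires at least one observed transition
  per edge and inherits birth-death assumptions (exchanges only between
  contiguous nodes — true for this engine).
* Block-averaged SEs assume blocks longer than the correlation time; for
  strongly metastable trajectories they can understate the true error, which
  is why recovery tests use 3-SE bands plus absolute tolerances where a
  closed-form truth exists.
* `numba` is a hard dependency; the kernels are compiled on first use
  (a few seconds, cached afterwards).
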