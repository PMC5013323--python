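# Methods

## Model and assumptions

`patchdyn` models two sub-groups X and Y choosing among m identical
patches. The assumptions are those of fast patch choice in a small
arena: travel time between patches is negligible, so the state is fully
described by per-patch occupancies; patches are identical, so any
uneven outcome is self-organized rather than environmental; and
interactions are purely attractive (β ∈ [0, 1] — agonistic behaviour is
deliberately outside the model, which is the point: segregation emerges
here without repulsion, from retention kinetics plus a shared carrying
capacity).

Two ingredients generate the dynamics:

* **Retention (positive feedback).** The rate at which an individual
  leaves a patch decreases with the patch's effective occupancy
  u = own-group count + β × other-group count, as a decreasing Hill
  function Ξ(u) = θ / (1 + (u/K)^n). It is maximal (θ) at an empty
  patch, half-maximal at u = K, and its steepness is set by the
  exponent n.
* **Crowding (negative feedback).** Joining speed is multiplied by
  γ = 1 − (X_i + Y_i)/S on the destination patch, reaching 0 at
  capacity. γ is evaluated on the destination before a move; values
  driven negative by round-off are treated as 0. Feasibility requires
  N_x + N_y ≤ mS.

The flux from patch j to i is γ_i Ξ_ji X_j (leaving rate on the source,
crowding on the destination), giving the conservative ODE system of the
README. For m = 2 and N_x = N_y = N the scaled variables
x_i = X_i/N, y_i = Y_i/N evolve under the same equations with
parameters s = S/N, k = K/N and the rate normalized to 1 at an empty
patch. With this normalization the scaled time unit is t = θT/N; an
equivalent unnormalized rate family Ξ ∝ 1/(K^n + u^n) differs only by
the constant factor k^n, i.e. by the choice of time unit, and changes
no steady state, stability verdict, bifurcation or stationary
distribution.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| N_x, N_y | group sizes | individuals | — |
| m | number of patches | — | 2 |
| S (s = S/N) | carrying capacity per patch | individuals | — |
| K (k = K/N) | retention half-effect occupancy | individuals | — |
| θ | maximal joining/leaving speed | 1/time | 1 (absorbed by scaling) |
| n | Hill exponent of the leaving rate | — | 2 |
| β_x, β_y | heterospecific attraction | — | — |

n = 2 is the default because it is the smallest integer exponent that
supports the multistable aggregation/segregation structure; at n = 1
the positive feedback is too weak to break symmetry and the evenly
dispersed state is the only steady state everywhere (this is verified,
not assumed, by the multistart search in the test suite and acceptance
script). β < 0 is rejected by construction.

## Steady states and stability

Conservation (x_1 + x_2 = y_1 + y_2 = 1) reduces the two-patch system
to (x_1, y_1); all root finding and linear algebra happen on this
reduced system because the raw four-variable Jacobian carries
structural zero eigenvalues along the conserved directions.

* **Root finding.** Damped Newton (scipy's `hybr`) from a deterministic
  seed set — the homogeneous point plus four corner-biased seeds — and
  200 uniform random seeds from a fixed RNG (fewer for dense parameter
  sweeps, where 40 random seeds suffice for a 2-D system). Roots are
  accepted at residual ‖f‖∞ < 1e−11, deduplicated at L∞ distance 1e−6,
  and sorted for determinism. The homogeneous state is a fixed point by
  symmetry and is always included.
* **Classification.** Tolerance 1e−3 on the defining equalities, with
  precedence dispersion > aggregation > segregation (the homogeneous
  state satisfies both semi-homogeneous equalities).
* **Stability.** Eigenvalues of the analytic 2×2 Jacobian (closed-form
  derivatives of the Hill and crowding factors); a central-difference
  Jacobian is kept as an independent cross-check and agrees to 1e−6.
  Stable means all real parts < −1e−7; oscillatory means a complex pair
  with positive real part. Hopf boundaries are located by bisection on
  the leading real part, tolerance 1e−4 in β.
* **Integration.** LSODA with rtol 1e−9/atol 1e−12; a terminal state is
  declared stationary when ‖rhs‖∞ < 1e−8, otherwise the trajectory is
  flagged non-convergent (the signature of the oscillatory regime).
  A fixed-step RK4 path, vectorized over many initial conditions, is
  provided for relaxation experiments (perturbing every equilibrium of
  a parameter grid at once); dt = 0.05–0.1 is stable because all rates
  are O(1) in scaled units.

## Stochastic counterpart

Integer populations move one individual at a time. The elementary
event attempt selects a candidate (group, source, destination) with
probability w/B, where w = γ_i Ξ_ji X_j is the mean-field flux of that
move and B = θ(N_x + N_y)(m − 1) is a fixed upper bound on the total
flux; with probability 1 − Σw/B nothing happens. This preserves the
model's relative rates exactly, conserves totals, and blocks joins to
full patches (w = 0 there). One **Monte Carlo step is one sweep of
N_x + N_y attempts**, so a step gives each individual one movement
opportunity on average: a single attempt per step leaves the ensemble
far from stationary after 1000 steps (only ~160 accepted moves for 48
individuals), whereas 1000 sweep-steps reproduce all the reference
regime topologies. In expectation one sweep advances the mean-field
clock by one scaled time unit, and in monostable regimes the ensemble
mean indeed tracks the deterministic trajectory under that mapping (to
within ~0.07 in occupied fraction at N = 24, a finite-size effect).

Initial conditions default to uniform-random feasible placement (each
individual picks a patch uniformly; the draw is rejected until capacity
holds), independently per realization — multistable regimes then
populate all basins, which is what makes the multi-peak histograms
visible. All realizations advance in lockstep from a single seeded RNG
stream (vectorized over the ensemble); identical configurations
reproduce bit-for-bit.

A two-patch chain small enough to enumerate (e.g. 2 + 2 individuals,
S = 3, seven feasible states) has its exact transition matrix built by
`exact_transition_matrix`; the empirical long-run occupation matches
the matrix's stationary eigenvector (χ², α = 0.01), tying the sampler
to the kinetics it claims to implement.

### Mode counting

Joint final-state histograms are smoothed with a 3×3 boxcar sum
(zero-padded) and peaks are extracted by a descending flood with
8-connectivity. A summit survives as a mode only if (i) its smoothed
mass is ≥ 0.02, (ii) its topographic prominence — height above the
saddle where its basin first meets a higher one — is at least
max(0.005, half its height), and (iii) it is not within Chebyshev
distance 2 of a stronger summit. Plain local-maximum counting
fragments the broad central peak of the dispersion regime into many
spurious summits at realistic ensemble sizes; prominence merging
removes them while leaving well-separated corner peaks untouched.
Ties are broken by raw cell mass, then lattice order, so a point-mass
histogram yields exactly one mode at its own cell.

## Segregation statistics

Duncan dissimilarity D = ½ Σ_i |X_i/N_x − Y_i/N_y| and per-group
Shannon entropy E = −Σ_i [(X_i/N_x) ln(X_i/N_x) + (Y_i/N_y) ln(Y_i/N_y)]
with 0 ln 0 = 0. The canonical configurations give exactly (1, 0) for
segregation, (0, 0) for aggregation and (0, 2 ln 2) for the well-mixed
state, and the two indices are coupled at their extremes (D = 1 forces
E = 0, and maximal E forces D = 0).

The random-placement baseline draws each group's patch-1 count
uniformly on {0..N} (capacity ignored). Per-individual coin-flip
placement is *not* used: it concentrates near the even split and yields
(≈0.16, ≈1.30) — uniform counts are the spread-out null whose means
approach the closed-form continuous limits E[D] → 1/3 and E[E] → 1 as
N grows. The exact finite-N expectations are computable by direct
summation (`exact_baseline_means`); at N = 12 they are (0.359, 0.911),
noticeably below the continuous limit for the entropy because the
13-point lattice includes the zero-entropy endpoints.

The population-proportion sweep holds N_x + N_y and S fixed (reference
conditions: totals 24 and 96 with S = 13 and 49, K = total/6,
β = 0.02), runs the stochastic ensemble at each proportion
N_x/(N_x + N_y) ∈ [0.5, 1), and reports index means and standard
deviations over final states. Imbalance between the groups pushes the
system from segregation toward aggregation/homogeneity; the inflexion
of each mean curve is located by the sign change of the discrete
second difference after a window-3 moving average.

## What the simulations do and do not emulate

The generator produces exactly the study conditions of the reference
regimes (N = 24 per group, K/N ∈ {0.1, 0.3}, S/N ∈ {2.5, 3, 6},
1000 sweep-steps, uniform random feasible starts). It does not emulate
spatial structure, travel time, individual heterogeneity within a
group, or repulsive interactions — so passing tests demonstrate the
internal consistency of the kinetics and the reproducibility of the
regime structure, not the behaviour of any particular species.

## Problem sizes used by the test suite

Deterministic sweeps use a 20×20 (β, s) grid at k ∈ {0.1, 0.3} with 30
random Newton seeds per cell; every steady state found is perturbed by
1e−3 in 20 random directions and relaxed by batched RK4 (all ~48,000
perturbations integrated jointly), with equilibria whose leading
eigenvalue lies within 2e−3 of the imaginary axis excluded as marginal
at that grid resolution. Stochastic regime checks use 2000
realizations × 1000 steps; the acceptance script's modal-location run
uses the full 10,000 realizations because the summit cell of the broad
central peak wanders ±3 lattice cells at 2000. The whole suite runs in
a few minutes on one core.

## Known limitations

* The asymmetric case is handled purely numerically; the ninth-degree
  polynomial reduction of the segregation branch is not implemented, so
  root completeness rests on the multistart density (which recovers the
  full nine-state structure wherever the symmetric case predicts it).
* Mode counting is tuned for (N+1)² lattices of two-patch ensembles;
  very small ensembles (≲500 realizations) leave lattice noise that can
  split or drown genuine peaks.
* The mean-field/ensemble-mean time mapping (one sweep = one scaled
  unit) holds in expectation; near bifurcation boundaries ensemble
  means mix basins and no longer track any single deterministic
  trajectory.
* `dimensional_rhs` accepts any m ≥ 2, but the analysis and stochastic
  layers are two-patch; multi-patch bifurcation structure is unexplored
  territory for this package.
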