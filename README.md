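# patchdyn

Aggregation–segregation dynamics of two interacting sub-groups (species,
strains, or castes) distributing themselves over identical resource
patches under a shared carrying capacity.

Mixed-species groups can disperse evenly, aggregate together in one
patch, segregate into different patches, or — under one-way attraction —
oscillate, *without any change in the individuals' behavioural rules*.
`patchdyn` implements the mean-field model of this phenomenon together
with its stochastic counterpart and the statistics used to quantify the
outcome, for researchers in collective animal behaviour and
self-organization who want to explore the parameter space or confront
the model with experiments.

## The model

Two populations X and Y (sizes N_x, N_y) move between m identical
patches of carrying capacity S. An individual of group X leaves patch j
for patch i at a rate that decreases with the patch's *effective
occupancy* — own-group occupants plus β_x times other-group occupants —
through a decreasing Hill function with threshold K and exponent n:

    Ξ_ji = θ / (1 + ((X_j + β_x Y_j)/K)^n)        (and Υ_ji with β_y for Y)

Joining a patch is slowed by crowding:

    γ_i = 1 − (X_i + Y_i)/S,    clipped to [0, 1]

so the flux of X individuals from j to i is γ_i Ξ_ji X_j, and

    dX_i/dT = Σ_{j≠i} [ γ_i Ξ_ji X_j − γ_j Ξ_ij X_i ]

with group totals conserved and the feasibility constraint
N_x + N_y ≤ mS. For two patches and equal group sizes
(N_x = N_y = N) the system nondimensionalizes to fractions
x_i = X_i/N, y_i = Y_i/N with scaled parameters s = S/N, k = K/N.

The two-patch symmetric system (β_x = β_y = β) has at most nine steady
states in four families: **dispersion** (all occupancies 1/2),
**aggregation** (x_1 = y_1 ≠ 1/2), **segregation** (x_1 = y_2 ≠ 1/2) and
**inhomogeneous** (all four distinct). Which of them exist and are
stable depends on (β, s, k); with one-way attraction (β_y = 0) the
homogeneous state can also lose stability through a complex eigenvalue
pair, producing sustained oscillations.

The stochastic counterpart moves one individual at a time with
probabilities proportional to the same fluxes; ensembles of realizations
yield joint final-state histograms whose mode count distinguishes the
regimes. Outcomes are scored by the Duncan dissimilarity index
D = ½ Σ_i |X_i/N_x − Y_i/N_y| (1 = fully segregated) and the
Shannon-type entropy E = −Σ_i [(X_i/N_x) ln(X_i/N_x) +
(Y_i/N_y) ln(Y_i/N_y)] (2 ln 2 = well mixed).

## Worked example

Steady states at s = 2.5, k = 0.3 under weak mutual attraction
(β = 0.05):

```sh
$ patchdyn equilibria --s 2.5 --k 0.3 --beta 0.05 --out eq
$ python -m json.tool eq.json   # abridged
segregation    x1=0.1159  y1=0.8841  stable=True
dispersion     x1=0.5000  y1=0.5000  stable=False
segregation    x1=0.8841  y1=0.1159  stable=True
```

Weak inter-attraction with a tight carrying capacity segregates the
groups: the two stable states place ~88% of one group and ~12% of the
other on the same patch, in mirror image, while the evenly-dispersed
state exists but is unstable. Raising β to 0.3 leaves only stable
dispersion; at β = 0.8 the groups aggregate together (run the same
command to see the branches move).

The same library calls are available in Python:

```python
from patchdyn import ScaledParams, find_steady_states
sp = ScaledParams(s=2.5, k=0.3, beta_x=0.05, beta_y=0.05)
for eq in find_steady_states(sp):
    print(eq.label, round(eq.x1, 4), eq.stable)
```

The random-placement reference level for the indices:

```sh
$ patchdyn baseline --nx 12 --ny 12 --reps 10000 --seed 7
{"duncan_mean": 0.3573, "duncan_std": 0.2564,
 "entropy_mean": 0.9098, "entropy_std": 0.3326}
```

i.e. randomly placed groups of 12 already show a mean dissimilarity of
~0.36, the yardstick against which the segregated (D → 1) and mixed
(D → 0) Monte Carlo outcomes are judged. Other subcommands: `simulate`
(Monte Carlo ensembles with histogram and mode output), `bifurcation`,
`state-diagram`, `dispersion-region`, `integrate`, `metrics`, `modes`,
`sweep-proportion`. Every run writes a `*.manifest.json` recording the
full parameter set and seed; rerunning a manifest's command reproduces
its outputs bit-for-bit.

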