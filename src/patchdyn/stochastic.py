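"""Individual-based Monte Carlo counterpart of the patch-choice model.

Integer populations move between patches one individual at a time.  The
elementary event is one attempt: a candidate move (group, source patch,
destination patch) is selected with probability proportional to the
corresponding mean-field flux gamma_i * Xi_ji * X_j, normalized by a fixed
upper bound on the total flux; the remaining probability yields a null
event (no move).  One Monte Carlo step is one sweep of N_x + N_y such
attempts, so a step gives each individual one movement opportunity on
average.  The chain reproduces the relative rates of the deterministic
model exactly, totals are conserved and destination capacity is enforced
(a full patch blocks joining).

Ensembles of realizations give the joint final-state histogram over
(X1/N_x, Y1/N_y) whose mode count distinguishes dispersion (one central
peak), aggregation or segregation (two corner peaks) and their
coexistence (four corner peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .model_core import DimensionalParams, PopulationState

__all__ = [
    "MCConfig",
    "EnsembleResult",
    "transition_weights",
    "exact_transition_matrix",
    "mc_step",
    "run_ensemble",
    "count_modes",
]


@dataclass(frozen=True)
class MCConfig:
    """Configuration of a Monte Carlo ensemble.

    ``init`` is either ``"uniform"`` (every individual assigned to a
    uniformly random patch, resampled until the capacity constraint
    holds, independently per realization) or an explicit pair of count
    vectors ``(X, Y)``.
    """

    params: DimensionalParams
    steps: int = 1000
    realizations: int = 10_000
    seed: int = 0
    init: object = "uniform"
    record_mean: bool = False

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


@dataclass
class EnsembleResult:
    """Final states of a Monte Carlo ensemble (two-patch system)."""

    finals: np.ndarray  # shape (realizations, 2): X1, Y1
    config: MCConfig
    mean_trajectory: np.ndarray | None = None  # (steps+1, 2) ensemble mean X1, Y1

    @property
    def histogram(self) -> np.ndarray:
        """Joint probability mass over the (N_x+1) x (N_y+1) count lattice."""
        p = self.config.params
        nx, ny = int(p.N_x), int(p.N_y)
        h = np.zeros((nx + 1, ny + 1))
        np.add.at(h, (self.finals[:, 0], self.finals[:, 1]), 1.0)
        return h / self.finals.shape[0]

    def modes(self, min_mass: float = 0.02, merge_radius: int = 2):
        return count_modes(self.histogram, min_mass=min_mass, merge_radius=merge_radius)

    def indices(self):
        """Duncan and entropy index of every final state (two arrays)."""
        from .metrics import duncan_index, entropy_index

        p = self.config.params
        d = np.empty(self.finals.shape[0])
        e = np.empty(self.finals.shape[0])
        for r, (x1, y1) in enumerate(self.finals):
            X = np.array([x1, p.N_x - x1], dtype=float)
            Y = np.array([y1, p.N_y - y1], dtype=float)
            d[r] = duncan_index(X, Y)
            e[r] = entropy_index(X, Y)
        return d, e


# ---------------------------------------------------------------------------
# Single-event kinetics
# ---------------------------------------------------------------------------

def transition_weights(state: PopulationState, p: DimensionalParams):
    """Enumerate candidate moves and their selection weights.

    Returns ``(events, weights, bound)`` where each event is
    ``(group, j, i)`` with group 0 = X, 1 = Y, and ``bound`` is the fixed
    normalization ``theta * (N_x + N_y) * (m - 1)`` that upper-bounds the
    total weight for every admissible state.  ``P(event) = w / bound``;
    the remainder is the null-event probability.
    """
    X, Y = state.x, state.y
    m = X.size
    tot = X + Y
    gamma = np.clip(1.0 - tot / p.S, 0.0, 1.0)
    xi = p.theta / (1.0 + ((X + p.beta_x * Y) / p.K) ** p.n_hill)
    ups = p.theta / (1.0 + ((Y + p.beta_y * X) / p.K) ** p.n_hill)
    events, weights = [], []
    for j in range(m):
        for i in range(m):
            if i == j:
                continue
            events.append((0, j, i))
            weights.append(gamma[i] * xi[j] * X[j])
            events.append((1, j, i))
            weights.append(gamma[i] * ups[j] * Y[j])
    bound = p.theta * (p.N_x + p.N_y) * (m - 1)
    return events, np.asarray(weights), bound


def mc_step(state: PopulationState, p: DimensionalParams, rng: np.random.Generator) -> PopulationState:
    """One event attempt: move at most one individual, or do nothing."""
    events, w, bound = transition_weights(state, p)
    r = rng.random() * bound
    c = np.cumsum(w)
    X = state.x.copy()
    Y = state.y.copy()
    idx = int(np.searchsorted(c, r, side="right"))
    if idx < len(events):
        g, j, i = events[idx]
        arr = X if g == 0 else Y
        arr[j] -= 1
        arr[i] += 1
    return PopulationState(X, Y, mode="integer")


def exact_transition_matrix(p: DimensionalParams):
    """Exhaustive one-step transition matrix of the two-patch chain.

    Enumerates every feasible integer state (X1, Y1) and fills the row
    with the per-event probabilities of :func:`transition_weights` (the
    diagonal absorbs null events).  Returns ``(states, P)``.
    """
    if p.m != 2:
        raise ValueError("exact enumeration implemented for m = 2")
    nx, ny = int(p.N_x), int(p.N_y)
    states = [
        (x1, y1)
        for x1 in range(nx + 1)
        for y1 in range(ny + 1)
        if x1 + y1 <= p.S and (nx - x1) + (ny - y1) <= p.S
    ]
    index = {st: i for i, st in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for st in states:
        i0 = index[st]
        x1, y1 = st
        ps = PopulationState(
            np.array([x1, nx - x1], float), np.array([y1, ny - y1], float), mode="integer"
        )
        events, w, bound = transition_weights(ps, p)
        stay = 1.0
        for (g, j, i), wk in zip(events, w):
            if wk <= 0:
                continue
            # patch-1 tally gains 1 iff the destination is patch 1, loses 1 iff the source is
            d1 = (1 if i == 0 else 0) - (1 if j == 0 else 0)
            tgt = (x1 + d1, y1) if g == 0 else (x1, y1 + d1)
            prob = wk / bound
            P[i0, index[tgt]] += prob
            stay -= prob
        P[i0, i0] += stay
    return states, P


# ---------------------------------------------------------------------------
# Ensembles (fast two-patch path)
# ---------------------------------------------------------------------------

def _rate_tables(p: DimensionalParams):
    """Lookup tables over the (X, Y) count lattice for the m = 2 loop."""
    nx, ny = int(p.N_x), int(p.N_y)
    Xg, Yg = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), indexing="ij")
    xi = p.theta / (1.0 + ((Xg + p.beta_x * Yg) / p.K) ** p.n_hill)
    ups = p.theta / (1.0 + ((Yg + p.beta_y * Xg) / p.K) ** p.n_hill)
    gamma = np.clip(1.0 - (Xg + Yg) / p.S, 0.0, 1.0)
    return xi, ups, gamma


def _draw_initial(p: DimensionalParams, rng: np.random.Generator):
    """Uniform-random feasible placement: each individual picks a patch."""
    nx, ny = int(p.N_x), int(p.N_y)
    S = p.S
    while True:
        x1 = int(rng.binomial(nx, 0.5))
        y1 = int(rng.binomial(ny, 0.5))
        if x1 + y1 <= S and (nx - x1) + (ny - y1) <= S:
            return x1, y1


def run_ensemble(cfg: MCConfig) -> EnsembleResult:
    """Run many realizations in lockstep and collect final (X1, Y1) counts.

    All realizations advance together (vectorized over the ensemble) from
    a single RNG stream seeded with ``cfg.seed``; identical configurations
    reproduce bit-for-bit.  Each of ``cfg.steps`` steps is one sweep of
    ``N_x + N_y`` event attempts.
    """
    p = cfg.params
    if p.m != 2:
        raise ValueError("ensembles are implemented for the two-patch system")
    if p.N_x + p.N_y > p.m * p.S:
        raise ValueError("infeasible initial condition: N_x + N_y > m*S")
    nx, ny = int(p.N_x), int(p.N_y)
    xi, ups, gamma = _rate_tables(p)
    bound = p.theta * (nx + ny) * (p.m - 1)
    R = cfg.realizations
    rng = np.random.default_rng(cfg.seed)

    if isinstance(cfg.init, str) and cfg.init == "uniform":
        x1 = rng.binomial(nx, 0.5, size=R)
        y1 = rng.binomial(ny, 0.5, size=R)
        bad = (x1 + y1 > p.S) | ((nx - x1) + (ny - y1) > p.S)
        while bad.any():
            nb = int(bad.sum())
            x1[bad] = rng.binomial(nx, 0.5, size=nb)
            y1[bad] = rng.binomial(ny, 0.5, size=nb)
            bad = (x1 + y1 > p.S) | ((nx - x1) + (ny - y1) > p.S)
    else:
        X0 = np.asarray(cfg.init[0])
        Y0 = np.asarray(cfg.init[1])
        if X0.sum() != nx or Y0.sum() != ny:
            raise ValueError("initial counts must sum to N_x and N_y")
        if np.any(X0 + Y0 > p.S):
            raise ValueError("initial counts violate patch capacity")
        x1 = np.full(R, int(X0[0]), dtype=np.int64)
        y1 = np.full(R, int(Y0[0]), dtype=np.int64)
    x1 = x1.astype(np.int64)
    y1 = y1.astype(np.int64)

    mean_traj = np.zeros((cfg.steps + 1, 2)) if cfg.record_mean else None
    if mean_traj is not None:
        mean_traj[0] = x1.mean(), y1.mean()
    attempts = nx + ny  # one sweep per step
    for step in range(cfg.steps):
        for _ in range(attempts):
            x2 = nx - x1
            y2 = ny - y1
            # cumulative fluxes: X 1->2, X 2->1, Y 1->2, Y 2->1
            w0 = gamma[x2, y2] * xi[x1, y1] * x1
            w1 = w0 + gamma[x1, y1] * xi[x2, y2] * x2
            w2 = w1 + gamma[x2, y2] * ups[x1, y1] * y1
            w3 = w2 + gamma[x1, y1] * ups[x2, y2] * y2
            u = rng.random(R) * bound
            x1 += (u >= w0) & (u < w1)
            x1 -= u < w0
            y1 += (u >= w2) & (u < w3)
            y1 -= (u >= w1) & (u < w2)
        if mean_traj is not None:
            mean_traj[step + 1] = x1.mean(), y1.mean()
    finals = np.stack([x1, y1], axis=1)
    return EnsembleResult(finals=finals, config=cfg, mean_trajectory=mean_traj)


# ---------------------------------------------------------------------------
# Mode counting
# ---------------------------------------------------------------------------

def count_modes(
    histogram: np.ndarray,
    min_mass: float = 0.02,
    merge_radius: int = 2,
    rel_prominence: float = 0.5,
    min_prominence: float = 0.005,
):
    """Count the peaks of a joint final-state histogram.

    The histogram is smoothed with a 3x3 boxcar sum (zero-padded) and its
    peaks are extracted by a descending flood with 8-connectivity: cells
    are visited from highest to lowest smoothed mass, and a local summit
    survives as a separate mode only if its topographic prominence -- its
    height above the saddle at which its basin first touches a higher
    one -- reaches ``max(min_prominence, rel_prominence * height)``.
    Prominence merging keeps the count robust to lattice noise on broad
    peaks while still resolving well-separated corner peaks.  Surviving
    summits must carry smoothed mass at least ``min_mass``; summits within
    Chebyshev distance ``merge_radius`` of a stronger one are merged into
    it.  Ties in smoothed mass are broken by raw cell mass, then lattice
    order, so a point-mass histogram yields exactly one mode at its cell.
    Returns a list of ``((i, j), smoothed_mass)`` sorted by mass.
    """
    h = np.asarray(histogram, dtype=float)
    if h.size == 0 or h.sum() <= 0:
        raise ValueError("empty histogram")
    sm = ndimage.uniform_filter(h, size=3, mode="constant", cval=0.0) * 9.0
    n_rows, n_cols = sm.shape
    flat_sm = sm.ravel()
    order = np.lexsort((np.arange(flat_sm.size), -h.ravel(), -flat_sm))

    comp = -np.ones(flat_sm.size, dtype=int)
    parent: dict[int, int] = {}
    peak: dict[int, tuple[float, tuple[int, int]]] = {}
    prominence: dict[int, float] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    next_id = 0
    for o in order:
        i, j = divmod(int(o), n_cols)
        neighbours = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < n_rows and 0 <= nj < n_cols:
                    c = comp[ni * n_cols + nj]
                    if c >= 0:
                        neighbours.add(find(int(c)))
        if not neighbours:
            comp[o] = next_id
            parent[next_id] = next_id
            peak[next_id] = (float(flat_sm[o]), (i, j))
            next_id += 1
        else:
            ranked = sorted(neighbours, key=lambda c: -peak[c][0])
            main = ranked[0]
            comp[o] = main
            for c in ranked[1:]:  # lower summits merge here: saddle level is flat_sm[o]
                prominence[c] = peak[c][0] - float(flat_sm[o])
                parent[c] = main
    for c in peak:
        if find(c) == c and c not in prominence:
            prominence[c] = peak[c][0]  # global summit: full height

    modes = [
        (ij, height)
        for c, (height, ij) in peak.items()
        if height >= min_mass
        and prominence[c] >= max(min_prominence, rel_prominence * height)
    ]
    modes.sort(key=lambda t: (-t[1], t[0]))
    kept: list[tuple[tuple[int, int], float]] = []
    for ij, mass in modes:
        if all(
            max(abs(ij[0] - kj[0]), abs(ij[1] - kj[1])) > merge_radius
            for (kj, _) in kept
        ):
            kept.append((ij, mass))
    return kept
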