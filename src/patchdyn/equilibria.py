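"""Steady states, stability and parameter sweeps of the two-patch model.

Conservation (x1 + x2 = 1, y1 + y2 = 1) reduces the scaled two-patch
system to two variables (x1, y1); all root finding and stability analysis
happens on that reduced system, whose Jacobian is free of the structural
zero modes the full four-variable system carries along the conserved
directions.

Steady states fall into four families: dispersion (all occupancies 1/2),
aggregation (x1 = y1 != 1/2, both groups together), segregation
(x1 = y2 != 1/2, the groups in different patches) and inhomogeneous
(all four occupancies distinct).  In the symmetric case (beta_x = beta_y)
at most nine steady states exist.  With asymmetric inter-attraction the
homogeneous state can lose stability through a complex eigenvalue pair,
yielding sustained oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .model_core import PopulationState, ScaledParams

__all__ = [
    "Equilibrium",
    "StateDiagram",
    "reduced_rhs",
    "jacobian",
    "find_steady_states",
    "classify",
    "stability",
    "bifurcation_diagram",
    "state_diagram",
    "dispersion_stability_region",
    "hopf_beta",
    "integrate_reduced",
]

#: classification tolerance on the defining equalities
CLASSIFY_TOL = 1e-3

#: deduplication tolerance (L-infinity) between distinct steady states
DEDUP_TOL = 1e-6

#: eigenvalue real parts within +-TOL_EIG of zero are treated as marginal
TOL_EIG = 1e-7

#: residual tolerance for accepting a root
ROOT_TOL = 1e-11


# ---------------------------------------------------------------------------
# Reduced system and Jacobian
# ---------------------------------------------------------------------------

def reduced_rhs(z, sp: ScaledParams):
    """RHS of the conservation-reduced system in (x1, y1).

    Vectorized: ``z`` may be shape (2,) or (n, 2).
    """
    z = np.asarray(z, dtype=float)
    x1 = z[..., 0]
    y1 = z[..., 1]
    x2 = 1.0 - x1
    y2 = 1.0 - y1
    g1 = np.clip(1.0 - (x1 + y1) / sp.s, 0.0, 1.0)
    g2 = np.clip(1.0 - (x2 + y2) / sp.s, 0.0, 1.0)
    n, k = sp.n_hill, sp.k
    A1 = 1.0 / (1.0 + ((x1 + sp.beta_x * y1) / k) ** n)
    A2 = 1.0 / (1.0 + ((x2 + sp.beta_x * y2) / k) ** n)
    B1 = 1.0 / (1.0 + ((y1 + sp.beta_y * x1) / k) ** n)
    B2 = 1.0 / (1.0 + ((y2 + sp.beta_y * x2) / k) ** n)
    f1 = g1 * A2 * x2 - g2 * A1 * x1
    f2 = g1 * B2 * y2 - g2 * B1 * y1
    return np.stack([f1, f2], axis=-1)


def _hill_and_deriv(u, k, n):
    h = 1.0 / (1.0 + (u / k) ** n)
    # d/du [1/(1+(u/k)^n)] = -(n/k)(u/k)^(n-1) h^2 ; u >= 0 (0**0 == 1 covers n=1)
    dp = (n / k) * (u / k) ** (n - 1.0)
    return h, -dp * h * h


def jacobian(z, sp: ScaledParams, method: str = "analytic", h: float = 1e-6):
    """2x2 Jacobian of :func:`reduced_rhs` at ``z = (x1, y1)``.

    ``method="analytic"`` differentiates the Hill and crowding forms in
    closed form; ``method="fd"`` uses central differences (step ``h``) and
    serves as an independent cross-check.
    """
    if method == "fd":
        z = np.asarray(z, dtype=float)
        J = np.empty((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            J[:, j] = (reduced_rhs(z + e, sp) - reduced_rhs(z - e, sp)) / (2 * h)
        return J
    if method != "analytic":
        raise ValueError("method must be 'analytic' or 'fd'")

    x1, y1 = float(z[0]), float(z[1])
    x2, y2 = 1.0 - x1, 1.0 - y1
    s, k, n = sp.s, sp.k, sp.n_hill
    bx, by = sp.beta_x, sp.beta_y

    g1_raw = 1.0 - (x1 + y1) / s
    g2_raw = 1.0 - (x2 + y2) / s
    g1, g2 = max(g1_raw, 0.0), max(g2_raw, 0.0)
    c1 = 1.0 if g1_raw > 0 else 0.0  # clamp indicator
    c2 = 1.0 if g2_raw > 0 else 0.0

    A1, dA1 = _hill_and_deriv(x1 + bx * y1, k, n)
    A2, dA2 = _hill_and_deriv(x2 + bx * y2, k, n)
    B1, dB1 = _hill_and_deriv(y1 + by * x1, k, n)
    B2, dB2 = _hill_and_deriv(y2 + by * x2, k, n)

    # f1 = g1*A2*x2 - g2*A1*x1
    df1_dx1 = (
        (-c1 / s) * A2 * x2 - g1 * dA2 * x2 - g1 * A2
        - (c2 / s) * A1 * x1 - g2 * dA1 * x1 - g2 * A1
    )
    df1_dy1 = (
        (-c1 / s) * A2 * x2 - g1 * dA2 * bx * x2
        - (c2 / s) * A1 * x1 - g2 * dA1 * bx * x1
    )
    # f2 = g1*B2*y2 - g2*B1*y1
    df2_dx1 = (
        (-c1 / s) * B2 * y2 - g1 * dB2 * by * y2
        - (c2 / s) * B1 * y1 - g2 * dB1 * by * y1
    )
    df2_dy1 = (
        (-c1 / s) * B2 * y2 - g1 * dB2 * y2 - g1 * B2
        - (c2 / s) * B1 * y1 - g2 * dB1 * y1 - g2 * B1
    )
    return np.array([[df1_dx1, df1_dy1], [df2_dx1, df2_dy1]])


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    """A steady state of the reduced system with its classification."""

    x1: float
    y1: float
    label: str = "unclassified"
    eigenvalues: np.ndarray | None = None
    stable: bool | None = None
    oscillatory: bool | None = None

    @property
    def state(self) -> PopulationState:
        return PopulationState(
            np.array([self.x1, 1.0 - self.x1]), np.array([self.y1, 1.0 - self.y1])
        )

    @property
    def z(self) -> np.ndarray:
        return np.array([self.x1, self.y1])


def classify(z, tol: float = CLASSIFY_TOL) -> str:
    """Label a steady state: dispersion > aggregation > segregation.

    Dispersion (all occupancies 1/2) satisfies both semi-homogeneous
    equalities, hence takes precedence; a state equal in neither sense is
    inhomogeneous.
    """
    x1, y1 = float(z[0]), float(z[1])
    if abs(x1 - 0.5) < tol and abs(y1 - 0.5) < tol:
        return "dispersion"
    if abs(x1 - y1) < tol:
        return "aggregation"
    if abs(x1 - (1.0 - y1)) < tol:
        return "segregation"
    return "inhomogeneous"


def _feasible(z, sp: ScaledParams, margin: float = 1e-9) -> bool:
    x1, y1 = z
    if not (-margin <= x1 <= 1 + margin and -margin <= y1 <= 1 + margin):
        return False
    return (x1 + y1 <= sp.s + margin) and ((1 - x1) + (1 - y1) <= sp.s + margin)


def _seed_points(sp: ScaledParams, n_starts: int, seed) -> np.ndarray:
    """Deterministic seeds (homogeneous + corner-biased) plus random ones."""
    det = np.array(
        [[0.5, 0.5], [0.95, 0.95], [0.95, 0.05], [0.05, 0.95], [0.05, 0.05]]
    )
    rng = np.random.default_rng(seed)
    rand = rng.uniform(0.0, 1.0, size=(max(n_starts, 0), 2))
    pts = np.vstack([det, rand])
    # project into the capacity-feasible strip 2 - s <= x1 + y1 <= s
    tot = pts.sum(axis=1)
    lo, hi = max(2.0 - sp.s, 0.0), min(sp.s, 2.0)
    shift = np.clip(tot, lo, hi) - tot
    return pts + shift[:, None] / 2.0


def find_steady_states(
    sp: ScaledParams,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = ROOT_TOL,
    classify_tol: float = CLASSIFY_TOL,
    with_stability: bool = True,
) -> list[Equilibrium]:
    """Locate all steady states by damped-Newton multistart.

    Roots of the reduced system are sought from a deterministic seed set
    (the homogeneous point and four corner-biased points) plus ``n_starts``
    uniform random seeds drawn from a fixed RNG, then deduplicated at
    L-infinity distance :data:`DEDUP_TOL`.  The homogeneous state is a
    fixed point by symmetry and is always present.  Results are sorted by
    (x1, y1) for determinism.
    """
    found: list[np.ndarray] = [np.array([0.5, 0.5])]
    for z0 in _seed_points(sp, n_starts, seed):
        sol = root(
            reduced_rhs,
            z0,
            args=(sp,),
            jac=lambda z, p: jacobian(z, p),
            method="hybr",
            tol=1e-13,
        )
        z = sol.x
        if not np.all(np.isfinite(z)):
            continue
        if np.max(np.abs(reduced_rhs(z, sp))) > tol:
            continue
        z = np.clip(z, 0.0, 1.0)
        if np.max(np.abs(reduced_rhs(z, sp))) > tol:
            continue  # clipping moved it off the root
        if not _feasible(z, sp):
            continue
        if all(np.max(np.abs(z - w)) > DEDUP_TOL for w in found):
            found.append(z)
    found.sort(key=lambda w: (round(w[0], 9), round(w[1], 9)))
    eqs = [
        Equilibrium(x1=float(z[0]), y1=float(z[1]), label=classify(z, classify_tol))
        for z in found
    ]
    if with_stability:
        eqs = [stability(eq, sp) for eq in eqs]
    return eqs


def stability(eq: Equilibrium, sp: ScaledParams, tol_eig: float = TOL_EIG) -> Equilibrium:
    """Attach eigenvalues and stability/oscillation verdicts to a steady state.

    Eigenvalues come from the analytic 2x2 Jacobian of the reduced system.
    Stable means all real parts below ``-tol_eig``; oscillatory means a
    complex pair with real part above ``+tol_eig`` (the route to sustained
    oscillations around the homogeneous state under asymmetric attraction).
    """
    lam = np.linalg.eigvals(jacobian(eq.z, sp))
    stable = bool(np.all(lam.real < -tol_eig))
    oscillatory = bool(np.any(np.abs(lam.imag) > 1e-9) and np.max(lam.real) > tol_eig)
    return replace(eq, eigenvalues=lam, stable=stable, oscillatory=oscillatory)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _with_beta(sp: ScaledParams, beta: float, vary: str) -> ScaledParams:
    if vary == "both":
        return replace(sp, beta_x=beta, beta_y=beta)
    if vary == "x":
        return replace(sp, beta_x=beta)
    raise ValueError("vary must be 'both' or 'x'")


def bifurcation_diagram(
    sp_base: ScaledParams,
    beta_grid: Sequence[float],
    vary: str | None = None,
    n_starts: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state branches as a function of the inter-attraction beta.

    Returns a long-format table with one row per (beta, equilibrium):
    columns beta, x1, y1, label, stable, oscillatory.  ``vary`` selects
    whether beta drives both attraction parameters (symmetric case) or
    only beta_x (asymmetric case, beta_y kept from ``sp_base``); by
    default it follows the symmetry of ``sp_base``.
    """
    if vary is None:
        vary = "both" if sp_base.symmetric else "x"
    rows = []
    for beta in beta_grid:
        sp = _with_beta(sp_base, float(beta), vary)
        for eq in find_steady_states(sp, n_starts=n_starts, seed=seed):
            rows.append(
                {
                    "beta": float(beta),
                    "x1": eq.x1,
                    "y1": eq.y1,
                    "label": eq.label,
                    "stable": eq.stable,
                    "oscillatory": eq.oscillatory,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StateDiagram:
    """Existing stable solution types on a (beta, s) grid at fixed k."""

    k: float
    beta_grid: np.ndarray
    s_grid: np.ndarray
    stable_labels: list[list[frozenset]]  # [i_s][i_beta]
    oscillatory: np.ndarray  # bool, shape (len(s_grid), len(beta_grid))
    symmetric: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.s_grid):
            for j, b in enumerate(self.beta_grid):
                rows.append(
                    {
                        "beta": float(b),
                        "s": float(s),
                        "k": self.k,
                        "labels": "+".join(sorted(self.stable_labels[i][j])) or "none",
                        "oscillatory": bool(self.oscillatory[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def region_count(self, labels: set[str] | frozenset) -> int:
        """Number of grid cells whose stable-label set equals ``labels``."""
        want = frozenset(labels)
        return sum(
            1 for row in self.stable_labels for cell in row if cell == want
        )


def state_diagram(
    k: float,
    beta_grid: Sequence[float],
    s_grid: Sequence[float],
    symmetric: bool = True,
    n_hill: float = 2.0,
    n_starts: int = 40,
    seed: int = 0,
) -> StateDiagram:
    """Map stable solution types over a (beta, s) grid at fixed k.

    In the asymmetric case (beta_y = 0) the oscillatory flag marks cells
    where the homogeneous state has an unstable complex eigenvalue pair.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    cells: list[list[frozenset]] = []
    osc = np.zeros((s_grid.size, beta_grid.size), dtype=bool)
    for i, s in enumerate(s_grid):
        row = []
        for j, b in enumerate(beta_grid):
            sp = ScaledParams(
                s=float(s),
                k=float(k),
                beta_x=float(b),
                beta_y=float(b) if symmetric else 0.0,
                n_hill=n_hill,
            )
            eqs = find_steady_states(sp, n_starts=n_starts, seed=seed)
            row.append(frozenset(eq.label for eq in eqs if eq.stable))
            osc[i, j] = any(
                eq.oscillatory and eq.label == "dispersion" for eq in eqs
            )
        cells.append(row)
    return StateDiagram(
        k=float(k),
        beta_grid=beta_grid,
        s_grid=s_grid,
        stable_labels=cells,
        oscillatory=osc,
        symmetric=symmetric,
    )


def dispersion_stability_region(
    beta_grid: Sequence[float],
    s_grid: Sequence[float],
    k_grid: Sequence[float],
    symmetric: bool = True,
    n_hill: float = 2.0,
) -> np.ndarray:
    """Stability of the homogeneous (dispersion) state over a 3-D grid.

    Returns a boolean array of shape (len(beta_grid), len(s_grid),
    len(k_grid)): True where the evenly-spread state is linearly stable.
    Stability prevails at low s or high k and depends weakly on beta.
    """
    out = np.zeros((len(beta_grid), len(s_grid), len(k_grid)), dtype=bool)
    z0 = np.array([0.5, 0.5])
    for a, b in enumerate(beta_grid):
        for i, s in enumerate(s_grid):
            for j, k in enumerate(k_grid):
                sp = ScaledParams(
                    s=float(s),
                    k=float(k),
                    beta_x=float(b),
                    beta_y=float(b) if symmetric else 0.0,
                    n_hill=n_hill,
                )
                lam = np.linalg.eigvals(jacobian(z0, sp))
                out[a, i, j] = bool(np.all(lam.real < -TOL_EIG))
    return out


def hopf_beta(
    sp_base: ScaledParams,
    beta_lo: float,
    beta_hi: float,
    tol: float = 1e-4,
) -> float:
    """Locate, by bisection in beta_x, the Hopf point of the homogeneous state.

    The bracket [beta_lo, beta_hi] must straddle a sign change of the real
    part of the homogeneous state's complex eigenvalue pair.
    """
    z0 = np.array([0.5, 0.5])

    def re_max(beta):
        lam = np.linalg.eigvals(jacobian(z0, replace(sp_base, beta_x=beta)))
        return float(np.max(lam.real))

    return float(brentq(re_max, beta_lo, beta_hi, xtol=tol))


# ---------------------------------------------------------------------------
# Vectorized relaxation (used to cross-check stability verdicts)
# ---------------------------------------------------------------------------

def integrate_reduced(
    z0: np.ndarray,
    sp: ScaledParams,
    t_end: float,
    dt: float = 0.05,
) -> np.ndarray:
    """Fixed-step RK4 on the reduced system, vectorized over initial states.

    ``z0`` has shape (n, 2); returns the states at ``t_end``.  Intended
    for relaxation experiments over many perturbations at once; for
    accurate single trajectories use :func:`patchdyn.model_core.integrate`.
    """
    z = np.array(z0, dtype=float)
    n_steps = max(int(round(t_end / dt)), 1)
    for _ in range(n_steps):
        k1 = reduced_rhs(z, sp)
        k2 = reduced_rhs(z + 0.5 * dt * k1, sp)
        k3 = reduced_rhs(z + 0.5 * dt * k2, sp)
        k4 = reduced_rhs(z + dt * k3, sp)
        z = z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(z, 0.0, 1.0, out=z)
    return z
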