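"""Mean-field model of two sub-groups distributing over identical patches.

Two populations X and Y (species, strains or castes) choose among ``m``
identical patches of carrying capacity ``S``.  Individuals leave a patch at
a rate that decreases with the patch's effective occupancy -- own-group
occupants plus ``beta`` times other-group occupants -- following a
decreasing Hill function with threshold ``K`` and exponent ``n_hill``.
Joining a patch is slowed by crowding: the joining speed is multiplied by
``1 - (X_i + Y_i)/S``, which vanishes when the patch is full.

The module provides the dimensional general-``m`` right-hand side, the
nondimensionalized two-patch form (occupancies as fractions, ``s = S/N``,
``k = K/N``), and trajectory integration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "DimensionalParams",
    "ScaledParams",
    "PopulationState",
    "Trajectory",
    "scale_parameters",
    "leaving_rate",
    "crowding_factor",
    "meanfield_rhs",
    "dimensional_rhs",
    "integrate",
    "params_from_dict",
    "params_to_dict",
    "load_params",
    "save_params",
]

#: default stationarity threshold on the max-norm of the RHS
STATIONARY_TOL = 1e-8

#: default integrator relative tolerance
INTEGRATOR_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionalParams:
    """Full parameterization of the m-patch, two-group model.

    Attributes
    ----------
    N_x, N_y : float
        Number of individuals in groups X and Y (continuous values are
        accepted by the mean-field equations).
    S : float
        Carrying capacity of each patch (individuals, both groups combined).
    K : float
        Response threshold of the leaving rate (individuals): at effective
        occupancy ``K`` the leaving rate is half its maximum.
    theta : float
        Maximal joining/leaving speed (1/time).
    n_hill : float
        Hill exponent of the leaving rate (>= 1); steepness of the
        occupancy response.
    beta_x : float
        Attraction of X individuals to Y occupants, in [0, 1].
    beta_y : float
        Attraction of Y individuals to X occupants, in [0, 1].
    m : int
        Number of patches (>= 2).
    """

    N_x: float
    N_y: float
    S: float
    K: float
    beta_x: float
    beta_y: float
    theta: float = 1.0
    n_hill: float = 2.0
    m: int = 2

    def __post_init__(self) -> None:
        for name in ("N_x", "N_y", "S", "K", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        for name in ("beta_x", "beta_y"):
            b = getattr(self, name)
            if not 0.0 <= b <= 1.0:
                raise ValueError(
                    f"{name} must lie in [0, 1]; repulsive (negative) "
                    "interactions are not part of the model"
                )
        if self.N_x + self.N_y > self.m * self.S + 1e-9:
            raise ValueError(
                "infeasible population: N_x + N_y must not exceed m*S "
                f"(got {self.N_x + self.N_y} > {self.m * self.S})"
            )


@dataclass(frozen=True)
class ScaledParams:
    """Nondimensional two-patch parameters for equal group sizes.

    Occupancies are fractions of the (common) group size N, ``s = S/N``,
    ``k = K/N``.  Feasibility of the two-patch system with equal groups
    requires ``s >= 1``.
    """

    s: float
    k: float
    beta_x: float
    beta_y: float
    n_hill: float = 2.0

    def __post_init__(self) -> None:
        if self.s <= 0 or self.k <= 0:
            raise ValueError("s and k must be strictly positive")
        if self.s < 1.0:
            raise ValueError(
                "s >= 1 required: two patches of scaled capacity s must be "
                "able to hold both unit-sized groups (2 <= m*s)"
            )
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        for name in ("beta_x", "beta_y"):
            b = getattr(self, name)
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def symmetric(self) -> bool:
        return self.beta_x == self.beta_y


def scale_parameters(p: DimensionalParams) -> ScaledParams:
    """Nondimensionalize a two-patch equal-group parameter set.

    ``s = S/N`` and ``k = K/N`` with ``N = N_x = N_y``; ``beta`` and the
    Hill exponent pass through unchanged.  The scaled form is defined only
    for equal group sizes; for ``N_x != N_y`` use :func:`dimensional_rhs`.
    """
    if p.N_x != p.N_y:
        raise ValueError(
            "scaling is defined for equal group sizes (N_x == N_y); "
            "use the dimensional form for unequal groups"
        )
    N = p.N_x
    return ScaledParams(
        s=p.S / N, k=p.K / N, beta_x=p.beta_x, beta_y=p.beta_y, n_hill=p.n_hill
    )


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Per-patch occupancies of both groups.

    ``x`` and ``y`` hold one entry per patch, either as fractions of each
    group (summing to 1, mode ``"fractional"``) or as integer counts
    (summing to N_x / N_y, mode ``"integer"``).
    """

    x: np.ndarray
    y: np.ndarray
    mode: str = "fractional"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.mode not in ("fractional", "integer"):
            raise ValueError("mode must be 'fractional' or 'integer'")
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("occupancies must be nonnegative")
        if self.mode == "fractional":
            for arr, name in ((self.x, "x"), (self.y, "y")):
                if abs(arr.sum() - 1.0) > 1e-9:
                    raise ValueError(f"fractional {name} must sum to 1")

    @property
    def m(self) -> int:
        return self.x.size

    @staticmethod
    def homogeneous(m: int = 2) -> "PopulationState":
        """The dispersion state: both groups split evenly across patches."""
        return PopulationState(np.full(m, 1.0 / m), np.full(m, 1.0 / m))


@dataclass
class Trajectory:
    """Time course of a mean-field integration (scaled time)."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), m)
    y: np.ndarray
    converged: bool
    final_rhs_norm: float

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(self.x[-1], self.y[-1])

    def to_frame(self):
        """Long-format table t, x1..xm, y1..ym."""
        import pandas as pd

        m = self.x.shape[1]
        data = {"t": self.t}
        for i in range(m):
            data[f"x{i + 1}"] = self.x[:, i]
        for i in range(m):
            data[f"y{i + 1}"] = self.y[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def leaving_rate(occ_own, occ_other, beta: float, sp: ScaledParams):
    """Scaled rate at which individuals leave a patch.

    A decreasing Hill function of the effective occupancy
    ``u = occ_own + beta * occ_other``::

        Xi(u) = 1 / (1 + (u / k)^n_hill)

    Maximal (= 1) at an empty patch, half-maximal at ``u = k``, and
    strictly decreasing: occupants -- weighted by the inter-attraction
    ``beta`` for the other group -- retain individuals on the patch.
    """
    occ_own = np.asarray(occ_own, dtype=float)
    occ_other = np.asarray(occ_other, dtype=float)
    if np.any(occ_own < 0) or np.any(occ_other < 0):
        raise ValueError("occupancies must be nonnegative")
    u = occ_own + beta * occ_other
    out = 1.0 / (1.0 + (u / sp.k) ** sp.n_hill)
    return out if out.shape else float(out)


def crowding_factor(total_occ, sp: ScaledParams):
    """Joining-speed reduction by patch crowding: ``1 - (x+y)/s`` in [0, 1].

    Equals 1 for an empty patch and 0 at capacity; a full patch admits
    nobody.  Raises on occupancies beyond capacity.
    """
    total_occ = np.asarray(total_occ, dtype=float)
    if np.any(total_occ < -1e-12):
        raise ValueError("total occupancy must be nonnegative")
    if np.any(total_occ > sp.s * (1.0 + 1e-9) + 1e-12):
        raise ValueError(
            f"capacity violated: total occupancy {float(np.max(total_occ))} "
            f"exceeds s = {sp.s}"
        )
    out = np.clip(1.0 - total_occ / sp.s, 0.0, 1.0)
    return out if out.shape else float(out)


def _pairwise_rhs(x, y, gamma, xi_x, xi_y):
    """Sum of fluxes j->i minus i->j for every patch pair (vectorized).

    flux of X from j to i is gamma_i * Xi(u_j) * x_j: the leaving rate is
    evaluated on the source patch, the crowding factor on the destination.
    """
    # outflow per source patch
    out_x = xi_x * x
    out_y = xi_y * y
    m = x.size
    # dx_i = gamma_i * sum_{j != i} out_x[j]  -  out_x[i] * sum_{j != i} gamma_j
    sum_out_x = out_x.sum()
    sum_out_y = out_y.sum()
    sum_gamma = gamma.sum()
    dx = gamma * (sum_out_x - out_x) - out_x * (sum_gamma - gamma)
    dy = gamma * (sum_out_y - out_y) - out_y * (sum_gamma - gamma)
    return dx, dy


def meanfield_rhs(state: PopulationState, sp: ScaledParams):
    """Scaled mean-field equations (fractional occupancies, m patches).

    dx_i/dt = sum_{j != i} [gamma_i Xi(u_j) x_j - gamma_j Xi(u_i) x_i]
    with u_j = x_j + beta_x y_j, and symmetrically for y with
    v_j = y_j + beta_y x_j.  Per-group totals are conserved exactly.
    """
    x, y = state.x, state.y
    gamma = crowding_factor(x + y, sp)
    xi_x = leaving_rate(x, y, sp.beta_x, sp)
    xi_y = leaving_rate(y, x, sp.beta_y, sp)
    return _pairwise_rhs(x, y, gamma, np.asarray(xi_x), np.asarray(xi_y))


def dimensional_rhs(state: PopulationState, p: DimensionalParams):
    """Dimensional equations for counts on m patches.

    dX_i/dT = sum_{j != i} [gamma_i Xi_ji X_j - gamma_j Xi_ij X_i] with
    Xi_ji = theta / (1 + ((X_j + beta_x Y_j)/K)^n) and
    gamma_i = 1 - (X_i + Y_i)/S.  Reduces to :func:`meanfield_rhs` (up to
    the time unit) after scaling when m = 2 and N_x = N_y.
    """
    X, Y = state.x, state.y
    if X.size != p.m:
        raise ValueError(f"state has {X.size} patches, params specify m = {p.m}")
    tot = X + Y
    if np.any(tot > p.S * (1.0 + 1e-9) + 1e-9):
        raise ValueError("capacity violated: X_i + Y_i exceeds S")
    gamma = np.clip(1.0 - tot / p.S, 0.0, 1.0)
    xi = p.theta / (1.0 + ((X + p.beta_x * Y) / p.K) ** p.n_hill)
    ups = p.theta / (1.0 + ((Y + p.beta_y * X) / p.K) ** p.n_hill)
    return _pairwise_rhs(X, Y, gamma, xi, ups)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(
    state0: PopulationState,
    sp: ScaledParams,
    t_end: float,
    rtol: float = INTEGRATOR_RTOL,
    stationary_tol: float = STATIONARY_TOL,
    n_out: int = 400,
) -> Trajectory:
    """Integrate the scaled mean-field equations to ``t_end``.

    Uses a stiff-capable adaptive method (LSODA).  The terminal state is
    flagged converged when ``||rhs||_inf < stationary_tol``; a
    non-converged trajectory typically signals sustained oscillation.
    """
    m = state0.m
    z0 = np.concatenate([state0.x, state0.y])

    def rhs(_t, z):
        st = PopulationState.__new__(PopulationState)
        st.x = np.clip(z[:m], 0.0, None)
        st.y = np.clip(z[m:], 0.0, None)
        st.mode = "fractional"
        dx, dy = meanfield_rhs(st, sp)
        return np.concatenate([dx, dy])

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        z0,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        t_eval=np.linspace(0.0, t_end, n_out),
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    final = sol.y[:, -1]
    norm = float(np.max(np.abs(rhs(sol.t[-1], final))))
    return Trajectory(
        t=sol.t,
        x=sol.y[:m].T.copy(),
        y=sol.y[m:].T.copy(),
        converged=norm < stationary_tol,
        final_rhs_norm=norm,
    )


# ---------------------------------------------------------------------------
# Parameter-file I/O (flat key-value JSON or YAML)
# ---------------------------------------------------------------------------

_DIM_KEYS = {"N_x", "N_y", "S", "K"}
_SCALED_KEYS = {"s", "k"}


def params_from_dict(d: dict) -> DimensionalParams | ScaledParams:
    """Build a parameter set from a flat mapping.

    Dimensional sets carry ``{N_x, N_y, S, K, ...}``, scaled sets
    ``{s, k, beta_x, beta_y, ...}``; the two key families must not mix.
    """
    keys = set(d)
    if _DIM_KEYS <= keys:
        if keys & _SCALED_KEYS:
            raise ValueError("mixed dimensional and scaled parameter keys")
        return DimensionalParams(**d)
    if _SCALED_KEYS <= keys:
        return ScaledParams(**d)
    raise ValueError(
        "parameter mapping must contain either {N_x, N_y, S, K} or {s, k}"
    )


def params_to_dict(p: DimensionalParams | ScaledParams) -> dict:
    return {k: getattr(p, k) for k in p.__dataclass_fields__}


def load_params(path) -> DimensionalParams | ScaledParams:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return params_from_dict(d)


def save_params(p, path) -> None:
    path = Path(path)
    d = params_to_dict(p)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")
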