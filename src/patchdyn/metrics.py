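"""Segregation and aggregation statistics for two-group patch occupancies.

Two complementary indices quantify how a final configuration distributes
the groups over patches:

* Duncan dissimilarity ``D = 1/2 * sum_i |X_i/N_x - Y_i/N_y|`` -- 0 when
  the two groups have identical per-patch proportions (aggregated or
  dispersed alike), 1 under complete segregation.
* Shannon-type entropy
  ``E = -sum_i [ (X_i/N_x) ln(X_i/N_x) + (Y_i/N_y) ln(Y_i/N_y) ]`` -- 0
  when each group sits entirely in one patch (segregated or aggregated),
  ``2 ln 2`` when both groups are spread evenly over two patches.

The random-placement baseline draws each group's patch-1 count uniformly
over its full range, which is the reference level against which the
Monte Carlo sweeps are read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import DimensionalParams
from .stochastic import MCConfig, run_ensemble

__all__ = [
    "IndexPair",
    "duncan_index",
    "entropy_index",
    "random_baseline",
    "proportion_sweep",
    "MAX_ENTROPY",
]

#: entropy of the well-mixed two-patch state
MAX_ENTROPY = 2.0 * math.log(2.0)


@dataclass(frozen=True)
class IndexPair:
    duncan: float
    entropy: float


def _check_counts(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("X and Y must be 1-D arrays of equal length")
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    nx, ny = X.sum(), Y.sum()
    if nx <= 0 or ny <= 0:
        raise ValueError("index undefined for an empty group")
    return X, Y, nx, ny


def duncan_index(X, Y) -> float:
    """Duncan dissimilarity of per-patch counts ``X`` and ``Y``.

    0 if the groups are distributed identically (all aggregated or all
    dispersed), 1 if fully segregated.
    """
    X, Y, nx, ny = _check_counts(X, Y)
    return float(0.5 * np.abs(X / nx - Y / ny).sum())


def entropy_index(X, Y) -> float:
    """Per-group Shannon entropy of the patch distribution (nats).

    0 when each group occupies a single patch, ``m ln m`` when both are
    spread evenly (``2 ln 2`` for two patches); ``0 ln 0 = 0``.
    """
    X, Y, nx, ny = _check_counts(X, Y)
    out = 0.0
    for p in np.concatenate([X / nx, Y / ny]):
        if p > 0:
            out -= p * math.log(p)
    return float(out)


def index_pair(X, Y) -> IndexPair:
    return IndexPair(duncan=duncan_index(X, Y), entropy=entropy_index(X, Y))


# ---------------------------------------------------------------------------
# Random-placement baseline
# ---------------------------------------------------------------------------

def random_baseline(
    N_x: int, N_y: int, realizations: int = 10_000, seed: int = 0
) -> dict:
    """Index statistics when the groups are placed at random (two patches).

    Per realization the patch-1 counts are drawn independently and
    uniformly: ``X_1 ~ U{0..N_x}``, ``Y_1 ~ U{0..N_y}`` (capacity is
    ignored).  Returns means and standard deviations of both indices.
    As the group sizes grow the means approach the continuous limits
    ``E[D] -> 1/3`` and ``E[E] -> 1``.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    rng = np.random.default_rng(seed)
    x1 = rng.integers(0, N_x + 1, size=realizations)
    y1 = rng.integers(0, N_y + 1, size=realizations)
    d = np.abs(x1 / N_x - y1 / N_y)  # two patches: D = |x1 - y1|

    def H(p):
        out = np.zeros_like(p, dtype=float)
        mask = (p > 0) & (p < 1)
        q = p[mask]
        out[mask] = -q * np.log(q) - (1 - q) * np.log(1 - q)
        return out

    e = H(x1 / N_x) + H(y1 / N_y)
    return {
        "duncan_mean": float(d.mean()),
        "duncan_std": float(d.std(ddof=0)),
        "entropy_mean": float(e.mean()),
        "entropy_std": float(e.std(ddof=0)),
    }


def exact_baseline_means(N_x: int, N_y: int) -> IndexPair:
    """Closed-form expectations of the uniform-count baseline.

    Computed by direct summation over the (N_x+1) x (N_y+1) lattice of
    equally likely count pairs; the continuous limits are (1/3, 1).
    """
    jx = np.arange(N_x + 1) / N_x
    jy = np.arange(N_y + 1) / N_y
    d = np.abs(jx[:, None] - jy[None, :]).mean()

    def H(p):
        p = p[(p > 0) & (p < 1)]
        return float(np.sum(-p * np.log(p) - (1 - p) * np.log(1 - p)))

    ex = H(jx) / (N_x + 1) + H(jy) / (N_y + 1)
    return IndexPair(duncan=float(d), entropy=ex)


# ---------------------------------------------------------------------------
# Population-proportion sweep
# ---------------------------------------------------------------------------

def proportion_sweep(
    total: int,
    S: float,
    proportions,
    beta: float = 0.02,
    steps: int = 1000,
    realizations: int = 2000,
    seed: int = 0,
    n_hill: float = 2.0,
) -> pd.DataFrame:
    """Index statistics versus group-size imbalance at fixed total population.

    For each proportion ``p = N_x/(N_x+N_y)`` in [0.5, 1) the stochastic
    ensemble is run with ``N_x = round(p*total)``, ``N_y = total - N_x``,
    the response threshold ``K = total/6`` and symmetric inter-attraction
    ``beta``; means and standard deviations of both indices over the
    final states are tabulated.  Imbalance pushes the system away from
    segregation toward aggregation/homogeneity, producing an inflexion in
    both mean curves (more marked at large totals); see
    :func:`inflexion_point`.
    """
    rows = []
    for prop in np.atleast_1d(np.asarray(proportions, dtype=float)):
        N_x = int(round(prop * total))
        N_y = total - N_x
        if N_y <= 0:
            raise ValueError(f"proportion {prop} leaves group Y empty")
        p = DimensionalParams(
            N_x=N_x,
            N_y=N_y,
            S=S,
            K=total / 6.0,
            beta_x=beta,
            beta_y=beta,
            n_hill=n_hill,
        )
        res = run_ensemble(
            MCConfig(params=p, steps=steps, realizations=realizations, seed=seed)
        )
        d, e = res.indices()
        rows.append(
            {
                "proportion": float(prop),
                "N_x": N_x,
                "N_y": N_y,
                "duncan_mean": d.mean(),
                "duncan_std": d.std(ddof=0),
                "entropy_mean": e.mean(),
                "entropy_std": e.std(ddof=0),
            }
        )
    return pd.DataFrame(rows)


def inflexion_point(proportions, means, window: int = 3):
    """Grid point where the discrete second difference changes sign.

    The mean curve is lightly smoothed (moving average, default window 3)
    before differencing; returns the first proportion at which the second
    difference changes sign, or ``None`` if the curve has no inflexion on
    the grid.
    """
    x = np.asarray(proportions, dtype=float)
    y = np.asarray(means, dtype=float)
    if y.size >= window:
        kernel = np.ones(window) / window
        pad = window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")
    d2 = np.diff(y, 2)
    sign = np.sign(d2)
    for i in range(len(sign) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            return float(x[i + 2])
    return None
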