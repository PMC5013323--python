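import numpy as np
import pytest

from patchdyn import DimensionalParams, MCConfig, run_ensemble

#: reference Monte Carlo study conditions: N = 24 individuals per group,
#: 1000 steps, with the ensemble size reduced to 2000 realizations
REGIMES = {
    "segregation": dict(S_mult=2.5, K_mult=0.3, beta_x=0.08, beta_y=0.08),
    "dispersion": dict(S_mult=2.5, K_mult=0.3, beta_x=0.3, beta_y=0.3),
    "aggregation": dict(S_mult=2.5, K_mult=0.3, beta_x=0.8, beta_y=0.8),
    "coexistence_asym": dict(S_mult=3.0, K_mult=0.1, beta_x=0.1, beta_y=0.0),
}


def regime_params(name: str, N: int = 24) -> DimensionalParams:
    r = REGIMES[name]
    return DimensionalParams(
        N_x=N,
        N_y=N,
        S=r["S_mult"] * N,
        K=r["K_mult"] * N,
        beta_x=r["beta_x"],
        beta_y=r["beta_y"],
    )


@pytest.fixture(scope="session")
def regime_ensembles():
    """Final-state ensembles for the four reference regime examples."""
    out = {}
    for name in REGIMES:
        cfg = MCConfig(
            params=regime_params(name), steps=1000, realizations=2000, seed=1
        )
        out[name] = run_ensemble(cfg)
    return out
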