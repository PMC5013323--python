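import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchdyn import (
    DimensionalParams,
    PopulationState,
    ScaledParams,
    crowding_factor,
    dimensional_rhs,
    integrate,
    leaving_rate,
    load_params,
    meanfield_rhs,
    params_from_dict,
    save_params,
    scale_parameters,
)


@pytest.fixture
def sp():
    return ScaledParams(s=2.5, k=0.3, beta_x=0.35, beta_y=0.1)


def random_state(rng, sp, m=2):
    """Admissible fractional state respecting per-patch capacity."""
    while True:
        x = rng.dirichlet(np.ones(m))
        y = rng.dirichlet(np.ones(m))
        if np.all(x + y <= sp.s):
            return PopulationState(x, y)


class TestParams:
    @pytest.mark.parametrize(
        "S_mult, K_mult, expected_s, expected_k",
        [(2.5, 0.3, 2.5, 0.3), (1.0, 1.0, 1.0, 1.0), (6.0, 0.25, 6.0, 0.25)],
    )
    def test_scaling(self, S_mult, K_mult, expected_s, expected_k):
        N = 24
        p = DimensionalParams(
            N_x=N, N_y=N, S=S_mult * N, K=K_mult * N, beta_x=0.3, beta_y=0.3
        )
        sp = scale_parameters(p)
        assert sp.s == pytest.approx(expected_s)
        assert sp.k == pytest.approx(expected_k)
        assert sp.beta_x == 0.3 and sp.n_hill == p.n_hill

    def test_unequal_groups_not_scalable(self):
        p = DimensionalParams(N_x=20, N_y=28, S=60, K=8, beta_x=0.1, beta_y=0.1)
        with pytest.raises(ValueError, match="dimensional"):
            scale_parameters(p)

    def test_total_population_feasibility(self):
        with pytest.raises(ValueError, match="m\\*S"):
            DimensionalParams(N_x=24, N_y=24, S=0.3 * 24, K=7.2, beta_x=0.1, beta_y=0.1)

    def test_repulsive_beta_rejected(self):
        with pytest.raises(ValueError):
            ScaledParams(s=2.5, k=0.3, beta_x=-0.2, beta_y=0.0)

    def test_roundtrip_config_files(self, tmp_path):
        for name, p in {
            "scaled.json": ScaledParams(s=2.5, k=0.3, beta_x=0.1, beta_y=0.0),
            "dim.yaml": DimensionalParams(
                N_x=24, N_y=24, S=60, K=7.2, beta_x=0.3, beta_y=0.3
            ),
        }.items():
            path = tmp_path / name
            save_params(p, path)
            assert load_params(path) == p

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            params_from_dict({"N_x": 1, "N_y": 1, "S": 3, "K": 1, "s": 2, "k": 0.1})


class TestRates:
    def test_empty_patch_is_maximal(self, sp):
        assert leaving_rate(0.0, 0.0, sp.beta_x, sp) == 1.0

    def test_half_effect_at_threshold(self):
        # Hill form forces rate = 1/2 exactly at effective occupancy k
        sp = ScaledParams(s=2.5, k=0.3, beta_x=0.5, beta_y=0.5)
        assert leaving_rate(0.3, 0.0, 0.0, sp) == pytest.approx(0.5)
        assert leaving_rate(0.1, 0.4, 0.5, sp) == pytest.approx(0.5)

    def test_monotone_decreasing_in_effective_occupancy(self, sp):
        occ = np.linspace(0, 1, 50)
        rates = leaving_rate(occ, 0.2, sp.beta_x, sp)
        assert np.all(np.diff(rates) < 0)

    def test_negative_occupancy_rejected(self, sp):
        with pytest.raises(ValueError):
            leaving_rate(-0.1, 0.0, 0.0, sp)

    def test_crowding_limits(self, sp):
        assert crowding_factor(0.0, sp) == 1.0
        assert crowding_factor(sp.s, sp) == 0.0
        assert crowding_factor(sp.s / 2, sp) == pytest.approx(0.5)

    def test_crowding_capacity_violation(self, sp):
        with pytest.raises(ValueError, match="capacity"):
            crowding_factor(sp.s + 0.1, sp)


class TestMeanFieldRHS:
    def test_homogeneous_state_is_fixed_point(self):
        sp = ScaledParams(s=2.5, k=0.3, beta_x=0.3, beta_y=0.3)
        dx, dy = meanfield_rhs(PopulationState.homogeneous(), sp)
        assert np.allclose(dx, 0, atol=1e-15) and np.allclose(dy, 0, atol=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        sp = ScaledParams(
            s=float(rng.uniform(1.0, 6.0)),
            k=float(rng.uniform(0.05, 1.0)),
            beta_x=float(rng.uniform(0, 1)),
            beta_y=float(rng.uniform(0, 1)),
        )
        st_ = random_state(rng, sp)
        dx, dy = meanfield_rhs(st_, sp)
        assert abs(dx.sum()) < 1e-12 and abs(dy.sum()) < 1e-12

    def test_symmetry_equivariance(self):
        # patch swap and species swap commute with the flow when beta_x = beta_y
        sp = ScaledParams(s=2.5, k=0.2, beta_x=0.4, beta_y=0.4)
        st_ = PopulationState(np.array([0.7, 0.3]), np.array([0.2, 0.8]))
        dx, dy = meanfield_rhs(st_, sp)
        dxs, dys = meanfield_rhs(PopulationState(st_.x[::-1], st_.y[::-1]), sp)
        assert np.allclose(dx[::-1], dxs) and np.allclose(dy[::-1], dys)
        dxw, dyw = meanfield_rhs(PopulationState(st_.y, st_.x), sp)
        assert np.allclose(dx, dyw) and np.allclose(dy, dxw)

    def test_rhs_matches_short_step_finite_difference(self):
        sp = ScaledParams(s=2.5, k=0.3, beta_x=0.2, beta_y=0.2)
        st_ = PopulationState(np.array([0.6, 0.4]), np.array([0.3, 0.7]))
        dx, dy = meanfield_rhs(st_, sp)
        h = 1e-4
        tr = integrate(st_, sp, h, n_out=2)
        fd_x = (tr.x[-1] - tr.x[0]) / h
        fd_y = (tr.y[-1] - tr.y[0]) / h
        assert np.allclose(fd_x, dx, atol=1e-6)
        assert np.allclose(fd_y, dy, atol=1e-6)


class TestDimensionalRHS:
    def test_matches_scaled_form_after_nondimensionalization(self):
        # dX/dT = theta * N * dx/dt for equal groups on two patches
        rng = np.random.default_rng(7)
        N, theta = 24.0, 1.7
        p = DimensionalParams(
            N_x=N, N_y=N, S=2.5 * N, K=0.3 * N, beta_x=0.4, beta_y=0.1, theta=theta
        )
        sp = scale_parameters(p)
        for _ in range(100):
            st_ = random_state(rng, sp)
            dX, dY = dimensional_rhs(
                PopulationState(st_.x * N, st_.y * N, mode="integer"), p
            )
            dx, dy = meanfield_rhs(st_, sp)
            assert np.allclose(dX / (theta * N), dx, atol=1e-12)
            assert np.allclose(dY / (theta * N), dy, atol=1e-12)

    def test_full_patches_block_all_joining(self):
        p = DimensionalParams(N_x=24, N_y=24, S=24, K=7.2, beta_x=0.3, beta_y=0.3)
        st_ = PopulationState(
            np.array([12.0, 12.0]), np.array([12.0, 12.0]), mode="integer"
        )
        dX, dY = dimensional_rhs(st_, p)
        assert np.allclose(dX, 0) and np.allclose(dY, 0)

    def test_symmetric_three_patch_state_is_stationary(self):
        p = DimensionalParams(N_x=24, N_y=24, S=60, K=7.2, beta_x=0.3, beta_y=0.3, m=3)
        st_ = PopulationState(np.full(3, 8.0), np.full(3, 8.0), mode="integer")
        dX, dY = dimensional_rhs(st_, p)
        assert np.allclose(dX, 0, atol=1e-13) and np.allclose(dY, 0, atol=1e-13)

    def test_capacity_violation_rejected(self):
        p = DimensionalParams(N_x=24, N_y=24, S=24, K=7.2, beta_x=0.3, beta_y=0.3)
        st_ = PopulationState(np.array([20.0, 4.0]), np.array([10.0, 14.0]), mode="integer")
        with pytest.raises(ValueError, match="capacity"):
            dimensional_rhs(st_, p)


class TestIntegrate:
    def test_fixed_point_stays_put(self):
        sp = ScaledParams(s=2.5, k=0.3, beta_x=0.3, beta_y=0.3)
        tr = integrate(PopulationState.homogeneous(), sp, 100.0)
        assert tr.converged
        assert np.allclose(tr.x, 0.5, atol=1e-7)

    def test_conservation_along_trajectory(self):
        sp = ScaledParams(s=2.5, k=0.1, beta_x=0.8, beta_y=0.8)
        st0 = PopulationState(np.array([0.55, 0.45]), np.array([0.40, 0.60]))
        tr = integrate(st0, sp, 300.0)
        assert np.allclose(tr.x.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(tr.y.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(tr.x + tr.y <= sp.s + 1e-6)

    def test_aggregation_attractor_at_large_beta(self):
        # strong mutual attraction: both groups end up in the same patch
        sp = ScaledParams(s=2.5, k=0.1, beta_x=0.8, beta_y=0.8)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x1, y1 = rng.uniform(0.05, 0.95, 2)
            st0 = PopulationState(np.array([x1, 1 - x1]), np.array([y1, 1 - y1]))
            tr = integrate(st0, sp, 2000.0)
            assert tr.converged
            xf, yf = tr.x[-1, 0], tr.y[-1, 0]
            assert abs(xf - yf) < 1e-4
            assert abs(xf - 0.5) > 0.1

    def test_sustained_oscillation_flagged_nonconvergent(self):
        # one-way attraction: the homogeneous state is the only steady state
        # and is oscillatory-unstable; x1(t) keeps cycling
        sp = ScaledParams(s=2.8, k=0.3, beta_x=0.35, beta_y=0.0)
        st0 = PopulationState(np.array([0.52, 0.48]), np.array([0.5, 0.5]))
        tr = integrate(st0, sp, 3000.0, n_out=1500)
        assert not tr.converged

    def test_trajectory_csv_roundtrip(self, tmp_path):
        sp = ScaledParams(s=2.5, k=0.3, beta_x=0.3, beta_y=0.3)
        st0 = PopulationState(np.array([0.6, 0.4]), np.array([0.5, 0.5]))
        tr = integrate(st0, sp, 10.0, n_out=11)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t,x1,x2,y1,y2"
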