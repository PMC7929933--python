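"""Stochastic simulation: noise scaling, determinism, labels, boundaries."""

import numpy as np
import pytest
from dataclasses import replace

from grnprecision.model import FixedPoint, NetworkSpec, GRNParameters
from grnprecision import sde
from grnprecision.sde import (
    classify_state,
    expression_stats,
    mfpt,
    simulate_sde,
    tissue_boundary,
    TissueSimulation,
)


def _birth_death(alpha=10.0, delta=1.0, omega=100.0):
    spec = NetworkSpec(("A", "B"), np.zeros((2, 2), np.int8), np.zeros(2, np.int8))
    return GRNParameters(
        spec=spec, alpha=np.array([alpha, 1.0]), delta=np.array([delta, 1.0]),
        K=np.ones((2, 2)), n=np.ones((2, 2)), w=np.ones((2, 2)),
        K_s=np.ones(2), m_s=np.ones(2), w_s=np.zeros(2), w_b=np.ones(2),
        omega=omega,
    )


class TestSimulateSDE:
    def test_zero_noise_limit_tracks_ode(self, wt_model, wt_bistable_signal):
        from scipy.integrate import solve_ivp

        from grnprecision.model import rhs_deterministic

        params, _, _ = wt_model
        big = replace(params, omega=1e12)
        x0 = np.array([2.0, 1.0, 0.1])
        traj = simulate_sde(big, x0, wt_bistable_signal, duration=5.0, dt=0.01, seed=3)
        sol = solve_ivp(lambda t, y: rhs_deterministic(params, np.maximum(y, 0), wt_bistable_signal),
                        (0, 5.0), x0, t_eval=traj.times, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(traj.states, sol.y.T, atol=2e-2)

    def test_stationary_variance_matches_system_size(self):
        # 1-node birth-death: stationary mean alpha/delta, variance mean/Omega
        p = _birth_death(alpha=10.0, delta=1.0, omega=100.0)
        traj = simulate_sde(p, np.array([10.0, 1.0]), 0.0, duration=2000.0, dt=0.01,
                            seed=7, record_stride=10)
        x = traj.states[500:, 0]
        assert x.mean() == pytest.approx(10.0, rel=0.02)
        assert x.var() == pytest.approx(0.1, rel=0.10)

    def test_seed_determinism_bitwise(self, wt_model, wt_bistable_signal):
        params, _, _ = wt_model
        a = simulate_sde(params, np.ones(3), wt_bistable_signal, 2.0, dt=0.02, seed=11)
        b = simulate_sde(params, np.ones(3), wt_bistable_signal, 2.0, dt=0.02, seed=11)
        assert np.array_equal(a.states, b.states)
        c = simulate_sde(params, np.ones(3), wt_bistable_signal, 2.0, dt=0.02, seed=12)
        assert not np.array_equal(a.states, c.states)

    def test_states_stay_nonnegative(self, wt_model):
        params, _, _ = wt_model
        noisy = replace(params, omega=5.0)
        traj = simulate_sde(noisy, np.zeros(3), 0.5, duration=10.0, dt=0.02, seed=1)
        assert np.all(traj.states >= 0)

    def test_bad_dt_rejected(self, wt_model):
        params, _, _ = wt_model
        with pytest.raises(ValueError):
            simulate_sde(params, np.ones(3), 1.0, duration=1.0, dt=0.0)


class TestClassifyState:
    @pytest.fixture()
    def attractors(self):
        return [
            FixedPoint(np.array([2.0, 2.5, 0.1]), "stable", np.array([-1.0 + 0j]), "pMN"),
            FixedPoint(np.array([0.05, 0.05, 3.0]), "stable", np.array([-1.0 + 0j]), "p3"),
        ]

    def test_attractor_identity(self, attractors):
        assert classify_state(attractors[0].state, attractors) == "pMN"
        assert classify_state(attractors[1].state, attractors) == "p3"

    def test_midpoint_is_other(self, attractors):
        scale = np.ones(3)
        eps = 1e-3
        z = np.exp(0.5 * (np.log(attractors[0].state + eps) + np.log(attractors[1].state + eps))) - eps
        assert classify_state(z, attractors, scale=scale) == "other"

    def test_single_attractor_wins(self, attractors):
        assert classify_state(np.array([9.0, 9.0, 9.0]), attractors[:1]) == "pMN"


def _occupancy_tissue(frac, positions):
    """Synthetic TissueSimulation with a prescribed p3 occupancy profile."""
    M = len(positions)
    cells = 400
    labels = np.empty((M, cells), dtype=object)
    for k in range(M):
        n_p3 = int(round(frac[k] * cells))
        labels[k, :n_p3] = "p3"
        labels[k, n_p3:] = "pMN"
    return TissueSimulation(
        positions=np.asarray(positions), end_states=np.zeros((M, cells, 3)),
        state_labels=labels, duration=50.0, genotype="wt", attractors=[],
    )


class TestTissueBoundary:
    def test_step_occupancy(self):
        r = np.linspace(0, 1, 101)
        tis = _occupancy_tissue((r < 0.3).astype(float), r)
        b = tissue_boundary(tis)
        assert b.defined
        assert b.position == pytest.approx(0.3, abs=0.011)
        assert b.width <= 0.011

    def test_logistic_occupancy_closed_form(self):
        # 11-89% band of a logistic profile spans 2*ln(0.89/0.11)*w = 4.18 w
        w = 0.02
        r = np.linspace(0, 1, 201)
        frac = 1.0 / (1.0 + np.exp((r - 0.4) / w))
        b = tissue_boundary(_occupancy_tissue(frac, r))
        assert b.defined
        assert b.position == pytest.approx(0.4, abs=0.01)
        assert b.width == pytest.approx(2 * np.log(0.89 / 0.11) * w, rel=0.08)

    def test_no_crossing_flagged(self):
        r = np.linspace(0, 1, 21)
        b = tissue_boundary(_occupancy_tissue(np.full(21, 0.02), r))
        assert not b.defined
        assert "crossing" in b.reason


class TestMFPT:
    def test_monostable_gives_no_target(self, wt_model):
        params, profile, _ = wt_model
        res = mfpt(params, profile(0.9), n_cells=4, t_max=5.0, seed=1)
        assert res.reason != ""
        assert res.censored_fraction == 1.0

    def test_deep_bistable_mostly_censored(self, wt_model):
        from grnprecision import neuraltube as nt

        params, profile, _ = wt_model
        r_fold, r_end = nt.fold_position(params, profile)
        res = mfpt(params, profile(r_fold + 0.18), n_cells=20, t_max=20.0, seed=1)
        assert res.censored_fraction > 0.8

    def test_forward_faster_than_reverse(self, wt_model):
        """Hysteresis: pMN->p3 jumps are faster than p3->pMN at the same
        position in the heterogeneity region."""
        from grnprecision import neuraltube as nt

        params, profile, _ = wt_model
        r_fold, _ = nt.fold_position(params, profile)
        s = profile(r_fold + 0.03)
        fwd = mfpt(params, s, "pMN", "p3", n_cells=60, t_max=150.0, seed=4)
        rev = mfpt(params, s, "p3", "pMN", n_cells=60, t_max=150.0, seed=4)
        assert fwd.mean_exposure is not None
        assert rev.mean_exposure is None or rev.mean_exposure > fwd.mean_exposure

    def test_jump_time_decreases_with_signal(self, wt_model):
        from grnprecision import neuraltube as nt

        params, profile, _ = wt_model
        r_fold, _ = nt.fold_position(params, profile)
        times = []
        for off in (0.02, 0.05, 0.09):
            res = mfpt(params, profile(r_fold + off), n_cells=80, t_max=300.0, seed=5)
            times.append(res.mean_exposure)
        assert all(t is not None for t in times)
        assert times[0] < times[1] < times[2]


class TestExpressionStats:
    def test_constant_samples(self):
        stats = expression_stats(np.full((50, 2), 3.0))
        np.testing.assert_allclose(stats.cv_per_gene, 0.0)
        assert stats.rms_total == 0.0

    def test_rms_total_definitional(self, rng):
        # independent genes with variances 4 and 9: rms = sqrt(13)
        X = np.column_stack([
            rng.normal(50, 2.0, 200000),
            rng.normal(50, 3.0, 200000),
        ])
        stats = expression_stats(X)
        assert stats.rms_total == pytest.approx(np.sqrt(13.0), rel=0.02)

    def test_zero_mean_flagged(self):
        X = np.column_stack([np.zeros(10), np.ones(10) + np.arange(10) * 0.1])
        with pytest.warns(UserWarning):
            stats = expression_stats(X)
        assert np.isnan(stats.cv_per_gene[0])

    def test_covariance_psd(self, rng):
        X = rng.normal(size=(500, 3))
        stats = expression_stats(X)
        assert np.all(np.linalg.eigvalsh(stats.covariance) > -1e-12)


class TestTissueSimulation:
    def test_deterministic_limit_sharp_boundary(self, wt_model):
        params, profile, _ = wt_model
        big = replace(params, omega=1e10)
        tis = sde.simulate_tissue(big, profile, M=24, cells_per_position=3,
                                  duration=30.0, dt=0.02, seed=1,
                                  positions=np.linspace(0.1, 0.6, 24))
        b = tissue_boundary(tis)
        spacing = np.diff(tis.positions)[0]
        assert b.defined
        assert b.width <= spacing + 1e-12

    def test_label_fractions_sum_to_one(self, wt_model):
        params, profile, _ = wt_model
        tis = sde.simulate_tissue(params, profile, M=10, cells_per_position=8,
                                  duration=5.0, dt=0.02, seed=2,
                                  positions=np.linspace(0.1, 0.6, 10))
        for k in range(10):
            labs = tis.state_labels[k]
            assert sum(labs == lab for lab in ("pMN", "p3", "other")).sum() == 8

    def test_reproducible(self, wt_model):
        params, profile, _ = wt_model
        kw = dict(M=8, cells_per_position=5, duration=3.0, dt=0.02, seed=9,
                  positions=np.linspace(0.15, 0.5, 8))
        a = sde.simulate_tissue(params, profile, **kw)
        b = sde.simulate_tissue(params, profile, **kw)
        assert np.array_equal(a.end_states, b.end_states)
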