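"""Deterministic network core: rates, Jacobian, fixed points, bifurcations."""

import numpy as np
import pytest

from grnprecision.model import (
    ConfigurationError,
    DynamicalSystem,
    GRNParameters,
    MutantPerturbation,
    NetworkSpec,
    SignalProfile,
    apply_mutant,
    bifurcation_scan,
    find_fixed_points,
    jacobian,
    production_gain,
    rhs_batch,
    rhs_deterministic,
)


def _hill_act(u, K, m):
    return u**m / (u**m + K**m)


def _hill_rep(u, K, m):
    return K**m / (K**m + u**m)


def _reference_rhs(params, x, s):
    """Independent term-by-term evaluation of the model equations."""
    spec = params.spec
    out = np.empty(params.n_nodes)
    for i in range(params.n_nodes):
        if spec.signal_sign[i] > 0:
            g = params.w_b[i] + params.w_s[i] * _hill_act(s, params.K_s[i], params.m_s[i])
        elif spec.signal_sign[i] < 0:
            g = params.w_b[i] + params.w_s[i] * _hill_rep(s, params.K_s[i], params.m_s[i])
        else:
            g = params.w_b[i] + params.w_s[i]
        for j in range(params.n_nodes):
            sg = spec.sign[i, j]
            if sg == 0:
                continue
            h = _hill_act(x[j], params.K[i, j], params.n[i, j]) if sg > 0 else _hill_rep(
                x[j], params.K[i, j], params.n[i, j]
            )
            g *= 1.0 - params.w[i, j] + params.w[i, j] * h
        out[i] = params.alpha[i] * g - params.delta[i] * x[i]
    return out


def _single_node(alpha=2.0, delta=1.0):
    spec = NetworkSpec(("A", "B"), np.zeros((2, 2), np.int8), np.zeros(2, np.int8))
    return GRNParameters(
        spec=spec, alpha=np.array([alpha, 1.0]), delta=np.array([delta, 1.0]),
        K=np.ones((2, 2)), n=np.ones((2, 2)), w=np.ones((2, 2)),
        K_s=np.ones(2), m_s=np.ones(2), w_s=np.zeros(2), w_b=np.ones(2),
    )


class TestRHS:
    def test_unregulated_node_is_linear(self):
        p = _single_node(alpha=2.0, delta=1.0)
        f = rhs_deterministic(p, [1.0, 1.0], 0.5)
        assert f[0] == pytest.approx(1.0)  # alpha - delta * x

    def test_matches_independent_reference(self, wt_model, rng):
        params, _, _ = wt_model
        for _ in range(25):
            x = rng.uniform(0, 3, params.n_nodes)
            s = rng.uniform(0, 4)
            np.testing.assert_allclose(
                rhs_deterministic(params, x, s), _reference_rhs(params, x, s),
                rtol=0, atol=1e-12,
            )

    def test_batch_matches_scalar(self, wt_model, rng):
        params, _, _ = wt_model
        X = rng.uniform(0, 3, (10, params.n_nodes))
        batch = rhs_batch(params, X, 1.0)
        for k in range(10):
            np.testing.assert_allclose(batch[k], rhs_deterministic(params, X[k], 1.0))

    def test_gain_bounded(self, wt_model, rng):
        params, _, _ = wt_model
        for _ in range(50):
            G = production_gain(params, rng.uniform(0, 10, 3), rng.uniform(0, 6))
            assert np.all(G >= 0) and np.all(G <= 1)

    def test_negative_state_rejected(self, wt_model):
        params, _, _ = wt_model
        with pytest.raises(ValueError):
            rhs_deterministic(params, [-1.0, 0.0, 0.0], 1.0)

    def test_vanishes_at_fixed_points(self, wt_model, wt_bistable_signal):
        params, _, _ = wt_model
        for fp in find_fixed_points(params, wt_bistable_signal, n_starts=20):
            assert np.linalg.norm(rhs_deterministic(params, fp.state, wt_bistable_signal)) < 1e-8


class TestJacobian:
    def test_single_node_decay(self):
        p = _single_node(alpha=2.0, delta=1.5)
        J = jacobian(p, [1.0, 1.0], 0.0)
        assert J[0, 0] == pytest.approx(-1.5)

    def test_matches_finite_differences(self, wt_model, rng):
        params, _, _ = wt_model
        for _ in range(100):
            x = rng.uniform(0.05, 3, 3)
            s = rng.uniform(0.1, 4)
            J = jacobian(params, x, s)
            Jfd = np.zeros_like(J)
            for j in range(3):
                h = 1e-6 * max(x[j], 1.0)
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                Jfd[:, j] = (rhs_deterministic(params, xp, s) - rhs_deterministic(params, xm, s)) / (2 * h)
            np.testing.assert_allclose(J, Jfd, rtol=1e-5, atol=1e-7)

    def test_repression_offdiagonals_nonpositive(self, wt_model, rng):
        params, _, _ = wt_model
        sign = params.spec.sign
        for _ in range(20):
            J = jacobian(params, rng.uniform(0.05, 3, 3), rng.uniform(0.1, 4))
            assert np.all(J[sign < 0] <= 1e-12)


class TestFixedPoints:
    def test_decoupled_analytic(self):
        p = _single_node(alpha=2.0, delta=0.5)
        fps = find_fixed_points(p, 0.0, n_starts=8)
        assert len(fps) == 1
        np.testing.assert_allclose(fps[0].state, [4.0, 1.0], atol=1e-8)
        assert fps[0].stability == "stable"

    def test_cubic_custom_system(self):
        sys_ = DynamicalSystem(
            lambda x, s: x - x**3, lambda x, s: np.array([[1 - 3 * x[0] ** 2]]), n_dim=1
        )
        fps = find_fixed_points(sys_, 0.0, n_starts=30, seed=2)
        states = sorted(float(fp.state[0]) for fp in fps)
        np.testing.assert_allclose(states, [-1.0, 0.0, 1.0], atol=1e-8)
        stab = {round(float(fp.state[0])): fp.stability for fp in fps}
        assert stab[-1] == "stable" and stab[1] == "stable" and stab[0] == "saddle"

    def test_wt_bistable_with_labels(self, wt_model, wt_bistable_signal):
        params, _, _ = wt_model
        fps = find_fixed_points(params, wt_bistable_signal, n_starts=30)
        labels = {fp.label for fp in fps}
        assert {"pMN", "p3", "transition_point"} <= labels
        stable = [fp for fp in fps if fp.stability == "stable"]
        saddles = [fp for fp in fps if fp.stability == "saddle"]
        assert len(stable) >= 2 and len(saddles) >= 1

    def test_stability_consistent_with_eigenvalues(self, wt_model, wt_bistable_signal):
        params, _, _ = wt_model
        for fp in find_fixed_points(params, wt_bistable_signal, n_starts=20):
            re = np.real(fp.eigenvalues)
            if fp.stability == "stable":
                assert np.all(re < 0)
            elif fp.stability == "saddle":
                assert np.sum(re > 0) == 1

    def test_no_root_warns_not_raises(self):
        sys_ = DynamicalSystem(lambda x, s: np.ones_like(x), n_dim=1)
        with pytest.warns(UserWarning):
            assert find_fixed_points(sys_, 0.0, n_starts=3) == []


class TestBifurcation:
    def test_decoupled_has_no_bistability(self):
        p = _single_node()
        d = bifurcation_scan(p, np.linspace(0.1, 2.0, 12))
        assert d.bistable_interval is None
        assert d.hysteresis_gap == 0.0

    def test_fold_normal_form_location(self):
        sys_ = DynamicalSystem(
            lambda x, s: np.array([s - x[0] ** 2]),
            lambda x, s: np.array([[-2.0 * x[0]]]),
            n_dim=1,
        )
        grid = np.linspace(-0.5, 0.5, 21)
        d = bifurcation_scan(sys_, grid, n_starts=16)
        # branch followed downward from high s disappears at the fold s = 0
        assert d.folds, "no fold detected"
        assert min(abs(f) for f in d.folds) <= (grid[1] - grid[0]) + 1e-12

    def test_wt_hysteresis(self, wt_model):
        params, profile, _ = wt_model
        grid = np.linspace(profile(0.6), profile(0.1), 80)
        d = bifurcation_scan(params, grid, n_starts=8)
        assert d.bistable_interval is not None
        assert d.hysteresis_gap > 0

    def test_monotone_grid_required(self, wt_model):
        params, _, _ = wt_model
        with pytest.raises(ValueError):
            bifurcation_scan(params, [0.1, 0.3, 0.2])


class TestMutants:
    def test_identity_is_noop(self, wt_model):
        params, _, _ = wt_model
        out = apply_mutant(params, MutantPerturbation())
        np.testing.assert_array_equal(out.alpha, params.alpha)
        np.testing.assert_array_equal(out.w, params.w)

    def test_input_not_mutated(self, wt_model, wt_bistable_signal):
        params, _, cfg = wt_model
        alpha_before = params.alpha.copy()
        apply_mutant(params, MutantPerturbation(deleted_nodes=("Pax6",)))
        np.testing.assert_array_equal(params.alpha, alpha_before)

    def test_pax6_deletion_zeroes_production(self, wt_model):
        params, _, _ = wt_model
        ko = apply_mutant(params, MutantPerturbation(deleted_nodes=("Pax6",)))
        assert ko.alpha[ko.index("Pax6")] == 0.0

    def test_scaling_groups(self, wt_model):
        params, _, _ = wt_model
        m = MutantPerturbation(scalings={
            "signal_weight:Olig2": 0.5,
            "edge_weight:Nkx2.2->Olig2": 0.5,
        })
        out = apply_mutant(params, m)
        io, in_ = out.index("Olig2"), out.index("Nkx2.2")
        assert out.w_s[io] == pytest.approx(0.5 * params.w_s[io])
        assert out.w[io, in_] == pytest.approx(0.5 * params.w[io, in_])

    def test_unknown_node_rejected(self, wt_model):
        params, _, _ = wt_model
        with pytest.raises(ConfigurationError):
            apply_mutant(params, MutantPerturbation(deleted_nodes=("Gli3",)))

    def test_olig2_induction_delayed_in_o2e33(self, wt_model):
        """Reduced enhancer input delays Olig2 induction: under a signal
        that ramps up as the gradient forms, the mutant crosses a fixed
        Olig2 level strictly later than wild type."""
        from scipy.integrate import solve_ivp

        from grnprecision.config import build_mutant

        params, profile, cfg = wt_model
        mut = apply_mutant(params, build_mutant(cfg, "o2e33"))
        s_target = profile(0.35)
        ramp = 25.0
        x0 = np.array([3.0, 0.1, 0.0])

        def crossing_time(p, level=1.0):
            def rhs(t, y):
                s = s_target * min(t / ramp, 1.0)
                return rhs_deterministic(p, np.maximum(y, 0), s)

            sol = solve_ivp(rhs, (0, 50), x0, dense_output=True, rtol=1e-8)
            tt = np.linspace(0, 50, 4000)
            vals = sol.sol(tt)[p.index("Olig2")]
            above = vals >= level
            assert above.any(), "Olig2 never induced"
            return tt[np.argmax(above)]

        assert crossing_time(mut) > crossing_time(params)


class TestRateBounds:
    """Production is bounded by the regulatory gain: for any admissible
    state, -delta*x <= dx/dt <= alpha - delta*x."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        x=st.lists(st.floats(0.0, 50.0), min_size=3, max_size=3),
        s=st.floats(0.0, 50.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rates_bounded_by_gain(self, x, s, wt_model):
        params, _, _ = wt_model
        x = np.asarray(x)
        f = rhs_deterministic(params, x, s)
        assert np.all(f >= -params.delta * x - 1e-12)
        assert np.all(f <= params.alpha - params.delta * x + 1e-12)


class TestSignalProfile:
    def test_pole_value(self):
        prof = SignalProfile(s_max=4.0, lam=0.2)
        assert prof(0.0) == pytest.approx(4.0)

    def test_decay_length(self):
        prof = SignalProfile(s_max=4.0, lam=0.2)
        assert prof(0.2) == pytest.approx(4.0 / np.e)

    def test_monotone_without_noise(self, rng):
        prof = SignalProfile()
        r = np.sort(rng.uniform(0, 1, 50))
        s = prof(r)
        assert np.all(np.diff(s) <= 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            SignalProfile()(1.5)

    def test_noise_requires_rng_and_stays_nonnegative(self, rng):
        prof = SignalProfile(noise_sd=0.5)
        with pytest.raises(ValueError):
            prof(0.3)
        vals = [prof(0.9, rng=rng) for _ in range(200)]
        assert min(vals) >= 0.0
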