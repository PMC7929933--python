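"""Minimum action paths, effective energy barriers and path geometry.

Noise-driven transitions between attractors concentrate, in the small-noise
limit, on the minimiser of the Freidlin-Wentzell action

    S[phi] = (1/2) * integral (phi' - b(phi))^T a(phi)^{-1} (phi' - b(phi)) dt

with drift b and diffusion matrix a (diagonal here).  Minimising over the
time parameterisation leaves the geometric ("gMAM") functional

    S[phi] = integral ( |phi'|_a |b|_a - <phi', b>_a ) dalpha ,
    <u,v>_a = sum_i u_i v_i / a_i(x)

which we minimise over discretised paths pinned at a stable state and at
the transition point (saddle); the descent from the saddle to the target
attractor follows the deterministic flow and costs no action.  The running
(cumulative) action along the path is the effective energy profile; its
value at the saddle is the barrier that sets the exponential scale of the
fate jump time, ln tau ~ Omega * S.

For the chemical-Langevin model a_i(x) = alpha_i G_i(s,x) + delta_i x_i
(with the system-size factor Omega pulled out of the action and restored in
the jump-time estimate); a unit-diffusion mode is available for benchmark
gradient systems, for which the uphill action equals twice the potential
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .model import (
    DynamicalSystem,
    FixedPoint,
    GRNParameters,
    GRNSystem,
    production_gain,
    _as_system,
)


class ActionError(RuntimeError):
    pass


def _diffusion_many(model, sys_: DynamicalSystem, X, s, mode: str):
    """Diagonal diffusion a_i evaluated on a batch of states (..., N)."""
    X = np.asarray(X, float)
    if mode == "unit":
        return np.ones_like(X)
    if mode == "langevin":
        from .model import production_gain_batch

        params = model if isinstance(model, GRNParameters) else getattr(model, "params", None)
        if params is None:
            raise ActionError("langevin diffusion requires GRNParameters")
        Xp = np.maximum(X, 0.0)
        G = production_gain_batch(params, Xp, s)
        return np.maximum(params.alpha * G + params.delta * Xp, 1e-12)
    raise ActionError(f"unknown diffusion mode {mode!r}")


@dataclass
class TransitionPath:
    points: np.ndarray            # (P_total, N) source -> saddle -> target
    arc_param: np.ndarray         # normalised [0,1] path coordinate
    action_increments: np.ndarray # per segment (P_total-1,)
    cumulative_action: np.ndarray # (P_total,), running sum, 0 at source
    total_action: float           # action at the saddle (uphill barrier)
    saddle_index: int
    scale: np.ndarray             # per-coordinate expression scale
    s: float
    diffusion: str

    @property
    def uphill(self) -> np.ndarray:
        return self.points[: self.saddle_index + 1]


def _geom_action_segments(paths, b_many, a_many):
    """Per-segment geometric action increments.

    ``paths`` has shape (..., P, N); returns increments of shape (..., P-1).
    """
    mid = 0.5 * (paths[..., :-1, :] + paths[..., 1:, :])
    dx = np.diff(paths, axis=-2)
    b = b_many(mid)
    a = a_many(mid)
    gdx = np.sum(dx * dx / a, axis=-1)
    gb = np.sum(b * b / a, axis=-1)
    cross = np.sum(dx * b / a, axis=-1)
    return np.sqrt(np.maximum(gdx * gb, 0.0)) - cross


def minimize_action(
    model,
    s: float,
    source: FixedPoint,
    target_saddle: FixedPoint,
    target: FixedPoint | None = None,
    P: int = 31,
    tol: float = 1e-6,
    diffusion: str | None = None,
    max_outer: int = 6,
    maxiter: int = 400,
) -> TransitionPath:
    """Geometric minimum action path from ``source`` to ``target_saddle``.

    The path is discretised at P points with pinned endpoints, minimised
    with L-BFGS-B and re-parameterised to equal arc length between outer
    iterations until the action changes by less than ``tol``.  If
    ``target`` is given the zero-action downhill leg from the saddle to it
    (deterministic flow) is appended.
    """
    sys_ = _as_system(model)
    if source.stability != "stable":
        raise ActionError("source must be a stable fixed point")
    if target_saddle.stability != "saddle":
        raise ActionError("target_saddle misclassified: not a saddle")
    if diffusion is None:
        diffusion = "langevin" if isinstance(model, (GRNParameters, GRNSystem)) else "unit"
    x0, x1 = source.state, target_saddle.state
    if np.linalg.norm(x0 - x1) < 1e-12:
        raise ActionError("degenerate path: source equals saddle")

    def b_many(X):
        Xc = np.maximum(X, 0.0) if sys_.nonnegative else X
        return sys_.rhs_many(Xc, s)

    def a_many(X):
        return _diffusion_many(model, sys_, X, s, diffusion)

    t = np.linspace(0.0, 1.0, P)
    path = x0[None, :] * (1 - t)[:, None] + x1[None, :] * t[:, None]
    N = sys_.n_dim
    D = (P - 2) * N
    step = 1e-7 * max(float(np.max(np.abs(np.concatenate([x0, x1])))), 1.0)

    def action_of(z):
        pts = np.concatenate(
            [np.broadcast_to(x0, z.shape[:-2] + (1, N)),
             z,
             np.broadcast_to(x1, z.shape[:-2] + (1, N))],
            axis=-2,
        )
        return np.sum(_geom_action_segments(pts, b_many, a_many), axis=-1)

    def objective(zflat):
        return float(action_of(zflat.reshape(P - 2, N)))

    def gradient(zflat):
        # vectorised forward differences: one batched action evaluation
        z = zflat.reshape(P - 2, N)
        batch = np.broadcast_to(z, (D,) + z.shape).copy()
        batch.reshape(D, D)[np.arange(D), np.arange(D)] += step
        S0 = action_of(z)
        S1 = action_of(batch)
        return (S1 - S0) / step

    bounds = [(0.0, None)] * D if sys_.nonnegative else None
    S_prev = np.inf
    last = None
    for _ in range(max_outer):
        z0 = path[1:-1].ravel()
        res = optimize.minimize(
            objective, z0, jac=gradient, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        last = res
        path = np.vstack([x0, res.x.reshape(P - 2, N), x1])
        path = _equal_arclength(path)
        S = float(np.sum(_geom_action_segments(path, b_many, a_many)))
        if abs(S_prev - S) < tol:
            S_prev = S
            break
        S_prev = S
    if not np.isfinite(S_prev):
        raise ActionError(f"action minimisation failed (last action {last.fun if last else 'n/a'})")

    inc = np.maximum(_geom_action_segments(path, b_many, a_many), 0.0)
    points = path
    saddle_index = P - 1
    if target is not None:
        down = _downhill_leg(sys_, s, target_saddle, target)
        if len(down) > 1:
            points = np.vstack([path, down[1:]])
            inc = np.concatenate([inc, np.zeros(len(down) - 1)])
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    arc = arc / arc[-1] if arc[-1] > 0 else arc
    return TransitionPath(
        points=points,
        arc_param=arc,
        action_increments=inc,
        cumulative_action=cum,
        total_action=float(cum[saddle_index]),
        saddle_index=saddle_index,
        scale=np.maximum(sys_.scale, 1e-12),
        s=float(s),
        diffusion=diffusion,
    )


def _equal_arclength(path):
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return path
    f = interp1d(arc / arc[-1], path, axis=0)
    return f(np.linspace(0, 1, len(path)))


def _downhill_leg(sys_, s, saddle: FixedPoint, target: FixedPoint, n_pts: int = 30):
    """Deterministic flow from the saddle (kicked along its unstable
    direction toward the target) down to the target attractor."""
    J = sys_.jac(saddle.state, s)
    eigval, eigvec = np.linalg.eig(J)
    k = int(np.argmax(np.real(eigval)))
    v = np.real(eigvec[:, k])
    if np.dot(v, target.state - saddle.state) < 0:
        v = -v
    x_start = saddle.state + 1e-3 * np.linalg.norm(target.state - saddle.state) * v
    if sys_.nonnegative:
        x_start = np.maximum(x_start, 0.0)

    def rhs(t, x):
        return sys_.rhs(np.maximum(x, 0.0) if sys_.nonnegative else x, s)

    def close(t, x):
        return np.linalg.norm(x - target.state) - 1e-3 * max(np.linalg.norm(sys_.scale), 1e-9)

    close.terminal = True
    sol = solve_ivp(rhs, (0.0, 500.0), x_start, events=close, max_step=1.0, rtol=1e-8, atol=1e-10)
    pts = sol.y.T
    pts = np.vstack([saddle.state, pts, target.state])
    # thin to n_pts by arc length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return pts[:1]
    f = interp1d(arc / arc[-1], pts, axis=0)
    return f(np.linspace(0, 1, n_pts))


def barrier_profile(path: TransitionPath):
    """(cumulative action series, barrier at the transition point)."""
    return path.cumulative_action, float(path.cumulative_action[path.saddle_index])


def jump_time_estimate(barrier: float, omega: float, prefactor: float | None = None,
                       calibration: tuple | None = None) -> float:
    """Large-deviation jump-time estimate tau = C * exp(Omega * S).

    ``calibration`` = (tau_ref, barrier_ref) fixes the prefactor C from one
    directly simulated reference jump time.
    """
    if barrier < 0 or omega <= 0:
        raise ValueError("need barrier >= 0 and omega > 0")
    if prefactor is None:
        if calibration is None:
            raise ValueError("supply a prefactor or a calibration point")
        tau_ref, S_ref = calibration
        prefactor = tau_ref / np.exp(omega * S_ref)
    return float(prefactor * np.exp(omega * barrier))


def curvature_metric(path: TransitionPath):
    """Arc-length excess of the uphill leg over the straight chord
    (0 for a straight path), in scale-normalised coordinates.

    Returns (curvature, max perpendicular deviation / chord length).
    """
    up = path.uphill / path.scale
    if len(up) < 3:
        raise ValueError("uphill leg needs >= 3 points")
    chord = up[-1] - up[0]
    dist = np.linalg.norm(chord)
    if dist < 1e-12:
        raise ValueError("degenerate uphill leg: source equals saddle")
    arclen = float(np.sum(np.linalg.norm(np.diff(up, axis=0), axis=1)))
    rel = up - up[0]
    proj = np.outer(rel @ chord / dist**2, chord)
    perp = np.linalg.norm(rel - proj, axis=1)
    return arclen / dist - 1.0, float(perp.max() / dist)


def signal_sensitivity(model, s_ref: float, ds: float, stable_label: str = "pMN",
                       n_starts: int = 24, seed: int = 0, ref_state=None) -> float:
    """Rate of separation of the stable state and the transition point per
    unit signal: centred difference of the scaled distance over 2*ds.

    The stable state is selected by ``stable_label`` or, when ``ref_state``
    is given, as the stable point nearest that reference (in scaled
    coordinates); the transition point is the saddle nearest the selected
    stable state.
    """
    from .model import find_fixed_points

    sys_ = _as_system(model)
    scale = np.maximum(sys_.scale, 1e-12)

    def separation(s):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fps = find_fixed_points(model, s, n_starts=n_starts, seed=seed)
        stab = [fp for fp in fps if fp.stability == "stable" and
                (ref_state is not None or fp.label == stable_label or stable_label is None)]
        sad = [fp for fp in fps if fp.stability == "saddle"]
        if not stab or not sad:
            raise ActionError(
                f"bistability lost at s={s}: use a smaller ds than {ds}"
            )
        if ref_state is not None:
            st = min(stab, key=lambda fp: np.linalg.norm((fp.state - ref_state) / scale)).state
        else:
            st = stab[0].state
        sd = min(sad, key=lambda fp: np.linalg.norm((fp.state - st) / scale)).state
        return np.linalg.norm((st - sd) / scale)

    return float(abs(separation(s_ref + ds) - separation(s_ref - ds)) / (2 * ds))


def third_node_contribution(path: TransitionPath, node_index: int = 2) -> float:
    """Fraction of the (scale-normalised) uphill displacement carried by one
    node: its coordinate range divided by the summed ranges of all nodes."""
    up = path.uphill / path.scale
    if up.shape[1] < 3:
        raise ValueError("third-node contribution needs >= 3 nodes")
    ranges = up.max(axis=0) - up.min(axis=0)
    total = ranges.sum()
    if total == 0:
        return 0.0
    return float(ranges[node_index] / total)
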