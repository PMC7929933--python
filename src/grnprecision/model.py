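"""Deterministic core of the patterning gene-regulatory network.

The ventral neural tube is patterned by a graded Sonic Hedgehog (Shh) input
acting on a small cross-repressive transcription-factor circuit
(Pax6, Olig2, Nkx2.2, optionally Irx3).  Each gene is produced at a maximal
rate modulated by a product of Hill-type regulation terms and decays
linearly:

    dx_i/dt = alpha_i * G_i(s, x) - delta_i * x_i,      G_i in [0, 1]

where ``G_i`` multiplies a signal-input factor and one term per regulatory
edge.  An activating edge j -> i contributes ``1 - w + w * u^m/(u^m + K^m)``
and a repressing edge ``1 - w + w * K^n/(K^n + x_j^n)``; the weight
``w in (0, 1]`` sets the strength of the interaction (w = 1 is a pure Hill
term).  Signal targets carry a factor ``w_b + w_s * s^m/(s^m + K_s^m)``
with ``w_b + w_s <= 1`` so a basal (signal-independent) activity can coexist
with the graded input.

This module provides the right-hand side and exact Jacobian, multistart
fixed-point location with stability classification, branch continuation /
bifurcation scans (bistable interval, folds, hysteresis), mutant
perturbations (gene deletion, edge-strength scaling) and the morphogen
signal profile across the dorsoventral axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

ACTIVATION = 1
REPRESSION = -1
ABSENT = 0

_SIGN_NAMES = {"activation": ACTIVATION, "repression": REPRESSION, "absent": ABSENT}


class ConfigurationError(ValueError):
    """Raised when a network spec / parameter set is internally inconsistent."""


@dataclass(frozen=True)
class NetworkSpec:
    """Wiring of an N-node network: signs of edges and of the morphogen input.

    ``sign[i, j]`` is the effect of gene j on gene i (+1 activation,
    -1 repression, 0 absent).  ``signal_sign[i]`` is the effect of the
    morphogen on node i (0 for non-targets).
    """

    node_names: tuple
    sign: np.ndarray
    signal_sign: np.ndarray

    def __post_init__(self):
        n = len(self.node_names)
        if n < 2:
            raise ConfigurationError("need at least two nodes")
        sign = np.asarray(self.sign, dtype=np.int8)
        ssign = np.asarray(self.signal_sign, dtype=np.int8)
        if sign.shape != (n, n) or ssign.shape != (n,):
            raise ConfigurationError("shape mismatch between nodes and sign matrices")
        object.__setattr__(self, "sign", sign)
        object.__setattr__(self, "signal_sign", ssign)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def signal_targets(self) -> tuple:
        return tuple(int(i) for i in np.flatnonzero(self.signal_sign))

    def index(self, name: str) -> int:
        return self.node_names.index(name)


@dataclass(frozen=True)
class GRNParameters:
    """Full parameterisation of the Hill network plus the noise size Omega.

    Array entries K, n, w are meaningful only where ``spec.sign`` is
    non-zero; signal entries only where ``spec.signal_sign`` is non-zero.
    Omega is the system size (molecules per concentration unit): the
    chemical-Langevin noise amplitude on node i is
    sqrt((alpha_i G_i + delta_i x_i) / Omega).
    """

    spec: NetworkSpec
    alpha: np.ndarray
    delta: np.ndarray
    K: np.ndarray
    n: np.ndarray
    w: np.ndarray
    K_s: np.ndarray
    m_s: np.ndarray
    w_s: np.ndarray
    w_b: np.ndarray
    omega: float = 100.0

    def __post_init__(self):
        N = self.spec.n_nodes
        for nm in ("alpha", "delta", "K_s", "m_s", "w_s", "w_b"):
            arr = np.asarray(getattr(self, nm), dtype=float)
            if arr.shape != (N,):
                raise ConfigurationError(f"{nm} must have shape ({N},)")
            object.__setattr__(self, nm, arr)
        for nm in ("K", "n", "w"):
            arr = np.asarray(getattr(self, nm), dtype=float)
            if arr.shape != (N, N):
                raise ConfigurationError(f"{nm} must have shape ({N},{N})")
            object.__setattr__(self, nm, arr)
        if np.any(self.alpha < 0) or np.any(self.delta <= 0):
            raise ConfigurationError("alpha must be >= 0 and delta > 0")
        if self.omega <= 0:
            raise ConfigurationError("omega must be positive")
        mask = self.spec.sign != 0
        if np.any(self.K[mask] <= 0) or np.any(self.n[mask] <= 0):
            raise ConfigurationError("K and n must be positive on present edges")
        if np.any((self.w[mask] <= 0) | (self.w[mask] > 1)):
            raise ConfigurationError("edge weights must lie in (0, 1]")
        smask = self.spec.signal_sign != 0
        if np.any(self.K_s[smask] <= 0) or np.any(self.m_s[smask] <= 0):
            raise ConfigurationError("signal K and m must be positive on targets")
        if np.any(self.w_b + self.w_s > 1 + 1e-12) or np.any(self.w_s < 0) or np.any(self.w_b < 0):
            raise ConfigurationError("need 0 <= w_b, w_s and w_b + w_s <= 1")

    @property
    def n_nodes(self) -> int:
        return self.spec.n_nodes

    @property
    def scale(self) -> np.ndarray:
        """Per-gene expression scale alpha/delta (maximal steady level)."""
        return self.alpha / self.delta

    def index(self, name: str) -> int:
        return self.spec.index(name)


@dataclass(frozen=True)
class FixedPoint:
    state: np.ndarray
    stability: str                      # "stable" | "saddle" | "unstable"
    eigenvalues: np.ndarray
    label: str = "other"                # "pMN" | "p3" | "transition_point" | "other"

    def relabel(self, label: str) -> "FixedPoint":
        return replace(self, label=label)


@dataclass
class BifurcationDiagram:
    signal_grid: np.ndarray
    branches: list                       # per grid point: list of FixedPoint
    bistable_interval: tuple | None      # (s_lo, s_hi) or None
    folds: tuple                         # fold signal values found
    hysteresis_gap: float

    def n_stable(self, k: int) -> int:
        return sum(fp.stability == "stable" for fp in self.branches[k])


@dataclass(frozen=True)
class MutantPerturbation:
    """Genetic perturbation: node deletions and multiplicative scalings.

    Scaling keys name parameter groups:
      ``"signal_weight:<node>"``, ``"basal_weight:<node>"``,
      ``"edge_weight:<source>-><target>"``, ``"alpha:<node>"``.
    """

    deleted_nodes: tuple = ()
    scalings: dict = field(default_factory=dict)


IDENTITY_PERTURBATION = MutantPerturbation()


# ----------------------------------------------------------------------------
# dynamics


def _hill_act(u, K, m):
    um = np.power(u, m)
    return um / (um + np.power(K, m))


def _hill_rep(u, K, m):
    Km = np.power(K, m)
    return Km / (Km + np.power(u, m))


def production_gain(params: GRNParameters, state, s):
    """Regulatory gain G_i(s, x) in [0, 1] for each node."""
    x = np.asarray(state, dtype=float)
    if np.any(x < 0) or s < 0:
        raise ValueError("state and signal must be non-negative")
    spec = params.spec
    N = params.n_nodes
    G = params.w_b + np.where(
        spec.signal_sign > 0,
        params.w_s * _hill_act(s, params.K_s, params.m_s),
        np.where(spec.signal_sign < 0, params.w_s * _hill_rep(s, params.K_s, params.m_s), params.w_s),
    )
    # non-targets carry w_b=1, w_s=0 so their factor is exactly 1
    for i in range(N):
        for j in range(N):
            sg = spec.sign[i, j]
            if sg == 0:
                continue
            h = _hill_act(x[j], params.K[i, j], params.n[i, j]) if sg > 0 else _hill_rep(
                x[j], params.K[i, j], params.n[i, j]
            )
            G[i] *= 1.0 - params.w[i, j] + params.w[i, j] * h
    return G


def rhs_deterministic(params: GRNParameters, state, s):
    """dx/dt = alpha * G(s, x) - delta * x."""
    x = np.asarray(state, dtype=float)
    return params.alpha * production_gain(params, x, s) - params.delta * x


def production_gain_batch(params: GRNParameters, X, s):
    """Vectorised gain for a batch of states X with shape (..., N)."""
    X = np.asarray(X, dtype=float)
    spec = params.spec
    sig = np.where(
        spec.signal_sign > 0,
        params.w_b + params.w_s * _hill_act(s, params.K_s, params.m_s),
        np.where(
            spec.signal_sign < 0,
            params.w_b + params.w_s * _hill_rep(s, params.K_s, params.m_s),
            params.w_b + params.w_s,
        ),
    )
    G = np.broadcast_to(sig, X.shape).copy()
    for i, j in zip(*np.nonzero(spec.sign)):
        h = (
            _hill_act(X[..., j], params.K[i, j], params.n[i, j])
            if spec.sign[i, j] > 0
            else _hill_rep(X[..., j], params.K[i, j], params.n[i, j])
        )
        G[..., i] *= 1.0 - params.w[i, j] + params.w[i, j] * h
    return G


def rhs_batch(params: GRNParameters, X, s):
    """Vectorised drift for a batch of states X with shape (..., N)."""
    X = np.asarray(X, dtype=float)
    return params.alpha * production_gain_batch(params, X, s) - params.delta * X


def jacobian(params: GRNParameters, state, s):
    """Exact Jacobian of :func:`rhs_deterministic` at ``state``."""
    x = np.asarray(state, dtype=float)
    if np.any(x < 0) or s < 0:
        raise ValueError("state and signal must be non-negative")
    spec = params.spec
    N = params.n_nodes
    G = production_gain(params, x, s)
    J = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            sg = spec.sign[i, j]
            if sg == 0:
                continue
            K, m, w = params.K[i, j], params.n[i, j], params.w[i, j]
            h = _hill_act(x[j], K, m) if sg > 0 else _hill_rep(x[j], K, m)
            term = 1.0 - w + w * h
            # d/du of u^m/(u^m+K^m) = m K^m u^(m-1) / (u^m+K^m)^2
            u = x[j]
            denom = (np.power(u, m) + np.power(K, m)) ** 2
            dh = m * np.power(K, m) * np.power(u, m - 1.0) / denom if u > 0 else (
                m * np.power(K, m) * 0.0 if m != 1.0 else np.power(K, m) / denom
            )
            if m == 1.0 and u == 0.0:
                dh = 1.0 / np.power(K, 1.0)
            if sg < 0:
                dh = -dh
            # G excluding the (i,j) term, guarded against term == 0
            if term > 1e-300:
                G_wo = G[i] / term
            else:
                G_wo = _gain_excluding(params, x, s, i, j)
            J[i, j] += params.alpha[i] * G_wo * w * dh
    J -= np.diag(params.delta)
    return J


def _gain_excluding(params, x, s, i, skip_j):
    spec = params.spec
    if spec.signal_sign[i] > 0:
        g = params.w_b[i] + params.w_s[i] * _hill_act(s, params.K_s[i], params.m_s[i])
    elif spec.signal_sign[i] < 0:
        g = params.w_b[i] + params.w_s[i] * _hill_rep(s, params.K_s[i], params.m_s[i])
    else:
        g = params.w_b[i] + params.w_s[i]
    for j in range(params.n_nodes):
        if j == skip_j or spec.sign[i, j] == 0:
            continue
        h = (
            _hill_act(x[j], params.K[i, j], params.n[i, j])
            if spec.sign[i, j] > 0
            else _hill_rep(x[j], params.K[i, j], params.n[i, j])
        )
        g *= 1.0 - params.w[i, j] + params.w[i, j] * h
    return g


# ----------------------------------------------------------------------------
# generic dynamical-system wrapper (lets test systems reuse the fixed-point
# and continuation machinery)


class DynamicalSystem:
    """Minimal interface: ``rhs(x, s)``, ``jac(x, s)``, ``n_dim``, ``scale``."""

    def __init__(self, rhs, jac=None, n_dim=1, scale=1.0, nonnegative=False):
        self._rhs = rhs
        self._jac = jac
        self.n_dim = n_dim
        self.scale = np.broadcast_to(np.asarray(scale, float), (n_dim,)).copy()
        self.nonnegative = nonnegative

    def rhs(self, x, s):
        return np.asarray(self._rhs(np.asarray(x, float), s), float)

    def jac(self, x, s):
        if self._jac is not None:
            return np.asarray(self._jac(np.asarray(x, float), s), float)
        return _fd_jacobian(lambda y: self.rhs(y, s), np.asarray(x, float))

    def rhs_many(self, X, s):
        """Drift for a batch of states, shape (..., N)."""
        X = np.asarray(X, float)
        flat = X.reshape(-1, self.n_dim)
        out = np.stack([self.rhs(row, s) for row in flat])
        return out.reshape(X.shape)


class GRNSystem(DynamicalSystem):
    def __init__(self, params: GRNParameters):
        self.params = params
        super().__init__(
            lambda x, s: rhs_deterministic(params, x, s),
            lambda x, s: jacobian(params, x, s),
            n_dim=params.n_nodes,
            scale=params.scale,
            nonnegative=True,
        )

    def rhs_many(self, X, s):
        return rhs_batch(self.params, X, s)


def _fd_jacobian(f, x, rel_step=1e-6):
    n = x.size
    J = np.zeros((n, n))
    f0 = f(x)
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        xm = x.copy()
        xm[j] = max(xm[j] - h, 0.0) if np.all(x >= 0) else xm[j] - h
        J[:, j] = (f(xp) - f(xm)) / (xp[j] - xm[j])
        del f0
        f0 = None
    return J


def _as_system(obj) -> DynamicalSystem:
    if isinstance(obj, DynamicalSystem):
        return obj
    if isinstance(obj, GRNParameters):
        return GRNSystem(obj)
    raise TypeError("expected GRNParameters or DynamicalSystem")


# ----------------------------------------------------------------------------
# fixed points


_EIG_TOL = 1e-7


def _classify(eigs) -> str:
    re = np.real(eigs)
    if np.all(re < -_EIG_TOL):
        return "stable"
    n_pos = int(np.sum(re > _EIG_TOL))
    if n_pos == 1:
        return "saddle"
    return "unstable"


def find_fixed_points(
    model, s, n_starts: int = 40, seed: int = 0, tol: float = 1e-10, starts=None
):
    """Deduplicated roots of the deterministic flow at signal ``s``.

    Multistart Newton (scipy ``hybr``) from canonical corner states of the
    expression cube plus log-uniform random starts; roots merged within
    1e-6 of the largest expression scale and classified by the Jacobian
    eigenvalues.  Deterministic for a given seed.
    """
    sys_ = _as_system(model)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    N = sys_.n_dim
    scale = np.maximum(sys_.scale, 1e-12)
    pts = []
    if starts is not None:
        pts.extend(np.asarray(p, float) for p in starts)
    if sys_.nonnegative:
        # corners of the expression cube: each gene fully on or off
        for mask in range(2**N if N <= 6 else 0):
            bits = [(mask >> k) & 1 for k in range(N)]
            pts.append(scale * np.array(bits, float))
    lo = np.where(sys_.nonnegative, 1e-3 * scale, -2.0 * scale)
    hi = 2.0 * scale
    for _ in range(max(0, n_starts - len(pts))):
        if sys_.nonnegative:
            u = rng.uniform(np.log(1e-3), np.log(2.0), size=N)
            pts.append(scale * np.exp(u))
        else:
            pts.append(rng.uniform(lo, hi))
    roots = []
    for x0 in pts:
        try:
            sol = optimize.root(
                lambda x: sys_.rhs(np.abs(x) if sys_.nonnegative else x, s),
                x0,
                method="hybr",
                options={"xtol": 1e-12},
            )
        except (ValueError, FloatingPointError):
            continue
        if not sol.success:
            continue
        x = np.abs(sol.x) if sys_.nonnegative else sol.x
        if np.linalg.norm(sys_.rhs(x, s)) > max(tol, 1e-8):
            continue
        roots.append(x)
    merged = []
    merge_tol = 1e-6 * float(np.max(scale))
    for x in roots:
        if not any(np.linalg.norm(x - y) < merge_tol * 10 for y in merged):
            merged.append(x)
    if not merged:
        warnings.warn(f"no fixed point found at s={s!r}")
        return []
    out = []
    for x in sorted(merged, key=lambda v: tuple(v)):
        eigs = np.linalg.eigvals(sys_.jac(x, s))
        out.append(FixedPoint(state=x, stability=_classify(eigs), eigenvalues=eigs))
    if isinstance(model, GRNParameters) or isinstance(model, GRNSystem):
        params = model if isinstance(model, GRNParameters) else model.params
        out = _label_fixed_point_set(params, out)
    return out


def _label_fixed_point_set(params: GRNParameters, fps):
    """Label a set of fixed points found at one signal level.

    Saddles become transition points.  With two or more stable states the
    p3 / pMN identities are assigned comparatively (the Nkx2.2-dominated
    attractor is p3, the Olig2-dominated one pMN); a lone stable state is
    labelled by its expression signature.
    """
    out = [fp.relabel(_label_fixed_point(params, fp)) for fp in fps]
    names = params.spec.node_names
    if "Olig2" not in names or "Nkx2.2" not in names:
        return out
    stable_idx = [k for k, fp in enumerate(out) if fp.stability == "stable"]
    if len(stable_idx) < 2:
        return out
    scale = np.maximum(params.scale, 1e-12)
    io, in_ = names.index("Olig2"), names.index("Nkx2.2")
    rel = {k: out[k].state / scale for k in stable_idx}
    k_p3 = max(stable_idx, key=lambda k: rel[k][in_] - rel[k][io])
    k_pmn = max(stable_idx, key=lambda k: rel[k][io] - rel[k][in_])
    if k_p3 != k_pmn:
        if rel[k_p3][in_] > rel[k_p3][io] and rel[k_p3][in_] > 0.02:
            out[k_p3] = out[k_p3].relabel("p3")
        if rel[k_pmn][io] > rel[k_pmn][in_] and rel[k_pmn][io] > 0.1:
            out[k_pmn] = out[k_pmn].relabel("pMN")
    return out


def _label_fixed_point(params: GRNParameters, fp: FixedPoint) -> str:
    """Label attractors by expression signature (p3: Nkx2.2 high; pMN: Olig2
    high, Nkx2.2 low), saddles as transition points."""
    names = params.spec.node_names
    if "Olig2" not in names or "Nkx2.2" not in names:
        return "transition_point" if fp.stability == "saddle" else "other"
    if fp.stability == "saddle":
        return "transition_point"
    if fp.stability != "stable":
        return "other"
    scale = np.maximum(params.scale, 1e-12)
    rel = fp.state / scale
    o, n = rel[params.index("Olig2")], rel[params.index("Nkx2.2")]
    if n > 0.1 and n >= o:
        return "p3"
    if o > 0.25 and n < o:
        return "pMN"
    return "other"


# ----------------------------------------------------------------------------
# bifurcation scan


def bifurcation_scan(model, signal_grid, direction: str = "both", n_starts: int = 24, seed: int = 0):
    """Branch continuation across a monotone signal grid.

    Seeds root finding at each grid point from the previous point's roots
    (with a multistart fallback before declaring a fold), records the
    bistable interval, fold locations and the hysteresis gap between the
    forward and backward switch signals.
    """
    grid = np.asarray(signal_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("signal_grid must be strictly monotone")
    if grid[0] > grid[-1]:
        grid = grid[::-1]
    sys_ = _as_system(model)

    branches = []
    prev_roots = None
    for k, s in enumerate(grid):
        starts = [fp.state for fp in prev_roots] if prev_roots else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fps = find_fixed_points(model, s, n_starts=n_starts, seed=seed + k, starts=starts)
        branches.append(fps)
        prev_roots = fps

    n_stable = np.array([sum(fp.stability == "stable" for fp in b) for b in branches])
    bist = np.flatnonzero(n_stable >= 2)
    bistable_interval = (float(grid[bist[0]]), float(grid[bist[-1]])) if len(bist) else None

    s_fw = _switch_signal(sys_, model, grid, branches, forward=True)
    s_bw = _switch_signal(sys_, model, grid, branches, forward=False)
    folds = tuple(v for v in (s_fw, s_bw) if v is not None)
    gap = abs(s_fw - s_bw) if (s_fw is not None and s_bw is not None) else 0.0
    return BifurcationDiagram(
        signal_grid=grid,
        branches=branches,
        bistable_interval=bistable_interval,
        folds=folds,
        hysteresis_gap=float(gap),
    )


def _switch_signal(sys_, model, grid, branches, forward: bool):
    """Signal at which the branch followed from one end of the grid is lost."""
    order = range(len(grid)) if forward else range(len(grid) - 1, -1, -1)
    order = list(order)
    start_fps = [fp for fp in branches[order[0]] if fp.stability == "stable"]
    if not start_fps:
        return None
    cur = start_fps[0].state
    merge_tol = 1e-2 * float(np.max(np.maximum(sys_.scale, 1e-12)))
    for k in order[1:]:
        s = grid[k]
        sol = optimize.root(lambda x: sys_.rhs(np.abs(x) if sys_.nonnegative else x, s), cur, method="hybr")
        x = np.abs(sol.x) if sys_.nonnegative else sol.x
        ok = sol.success and np.linalg.norm(sys_.rhs(x, s)) < 1e-8
        if ok:
            eigs = np.linalg.eigvals(sys_.jac(x, s))
            ok = _classify(eigs) == "stable" and np.linalg.norm(x - cur) < 50 * merge_tol + 0.5 * np.linalg.norm(cur)
        if not ok:
            # fallback: does any nearby stable point continue the branch?
            cand = [
                fp.state
                for fp in branches[k]
                if fp.stability == "stable" and np.linalg.norm(fp.state - cur) < merge_tol * 5
            ]
            if cand:
                cur = cand[0]
                continue
            return float(grid[k])
        cur = x
    return None


# ----------------------------------------------------------------------------
# mutants


def apply_mutant(params: GRNParameters, perturbation: MutantPerturbation) -> GRNParameters:
    """Return a new parameter set with the perturbation applied (pure)."""
    names = params.spec.node_names
    alpha = params.alpha.copy()
    w = params.w.copy()
    w_s = params.w_s.copy()
    w_b = params.w_b.copy()
    for node in perturbation.deleted_nodes:
        if node not in names:
            raise ConfigurationError(f"unknown node {node!r}")
        alpha[names.index(node)] = 0.0
    for key, fac in perturbation.scalings.items():
        if not (0 < fac <= 1):
            raise ConfigurationError(f"scaling factor for {key!r} must lie in (0, 1]")
        kind, _, rest = key.partition(":")
        if kind == "alpha":
            alpha[_node_index(names, rest)] *= fac
        elif kind == "signal_weight":
            w_s[_node_index(names, rest)] *= fac
        elif kind == "basal_weight":
            w_b[_node_index(names, rest)] *= fac
        elif kind == "edge_weight":
            src, _, dst = rest.partition("->")
            w[_node_index(names, dst), _node_index(names, src)] *= fac
        else:
            raise ConfigurationError(f"unknown parameter group {key!r}")
    return replace(params, alpha=alpha, w=w, w_s=w_s, w_b=w_b)


def _node_index(names, name):
    if name not in names:
        raise ConfigurationError(f"unknown node {name!r}")
    return names.index(name)


# ----------------------------------------------------------------------------
# morphogen signal profile


@dataclass(frozen=True)
class SignalProfile:
    """Exponential morphogen gradient across the dorsoventral axis.

    ``s(r) = s_max * exp(-r / lam)`` for position fraction r in [0, 1]
    (0 = ventral pole).  Optional additive Gaussian noise of standard
    deviation ``noise_sd * s(r)`` models signalling-gradient noise; drawn
    per call via the supplied rng, truncated at zero.
    """

    s_max: float = 6.0
    lam: float = 0.15
    noise_sd: float = 0.0

    def __call__(self, r, rng=None):
        r = np.asarray(r, dtype=float)
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("position fraction must lie in [0, 1]")
        s = self.s_max * np.exp(-r / self.lam)
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            s = np.maximum(s * (1.0 + self.noise_sd * rng.standard_normal(s.shape)), 0.0)
        return s if s.shape else float(s)

    def inverse(self, s):
        """Position fraction at which the noise-free profile equals ``s``."""
        return float(np.clip(-self.lam * np.log(s / self.s_max), 0.0, 1.0))


def signal_profile(r, profile: SignalProfile | None = None, rng=None):
    return (profile or SignalProfile())(r, rng=rng)
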