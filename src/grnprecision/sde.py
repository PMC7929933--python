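"""Stochastic (chemical-Langevin) simulation of single cells and tissues.

The SDE model keeps the deterministic rates f_i = alpha_i G_i - delta_i x_i
and adds intrinsic-noise terms g_i dW_i with

    g_i(x) = sqrt((alpha_i G_i + delta_i x_i) / Omega)

so the system size Omega (molecules per concentration unit) sets the noise
magnitude: production and degradation events contribute independent shot
noise.  Integration is Euler-Maruyama with reflection at zero.

A tissue is an array of independent cells along the dorsoventral axis, each
seeing the local morphogen level; there is no cell-cell coupling.  End
states are assigned progenitor identities (pMN / p3 / other) by proximity
to the labelled attractors of the local deterministic system, and the p3
occupancy profile across positions yields the boundary position and width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import (
    FixedPoint,
    GRNParameters,
    MutantPerturbation,
    SignalProfile,
    apply_mutant,
    bifurcation_scan,
    find_fixed_points,
    rhs_deterministic,
)


class IntegrationError(RuntimeError):
    pass


def _param_arrays(p: GRNParameters):
    return (
        p.alpha,
        p.delta,
        p.spec.sign,
        p.K,
        p.n,
        p.w,
        p.spec.signal_sign,
        p.K_s,
        p.m_s,
        p.w_s,
        p.w_b,
    )


def _kernel_seed(seed, *salts):
    """Stable sub-seed below 2**31 derived from (seed, salts)."""
    ss = np.random.SeedSequence([int(seed)] + [int(s) for s in salts])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray
    seed: int
    s: float
    dt: float


@dataclass
class TissueSimulation:
    positions: np.ndarray                 # M dorsoventral fractions, ventral->dorsal
    end_states: np.ndarray                # (M, cells, N)
    state_labels: np.ndarray              # (M, cells) of {"pMN","p3","other"}
    duration: float
    genotype: str
    attractors: list                      # per position: list of FixedPoint

    @property
    def p3_fraction(self) -> np.ndarray:
        return (self.state_labels == "p3").mean(axis=1)


@dataclass
class NoiseStats:
    genes: tuple
    cv_per_gene: np.ndarray
    covariance: np.ndarray
    rms_total: float


@dataclass
class BoundaryResult:
    defined: bool
    position: float | None
    width: float | None
    reason: str = ""


@dataclass
class FPTResult:
    mean: float | None                    # mean over uncensored runs
    censored_fraction: float
    mean_exposure: float | None           # censoring-aware (exponential MLE)
    times: np.ndarray
    censored: np.ndarray
    reason: str = ""


# ---------------------------------------------------------------------------


def simulate_sde(
    params: GRNParameters, x0, s: float, duration: float, dt: float = 0.02,
    seed: int = 0, record_stride: int | None = None,
) -> Trajectory:
    """Euler-Maruyama trajectory of one cell at fixed signal ``s``."""
    x0 = np.asarray(x0, dtype=float)
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    n_steps = int(round(duration / dt))
    stride = record_stride or max(1, n_steps // 2000)
    states, ok = _kernels.em_trajectory(
        x0, float(s), n_steps, stride, dt, params.omega,
        _kernel_seed(seed), *_param_arrays(params),
    )
    if not ok:
        raise IntegrationError(f"state blow-up: time step dt={dt} too large")
    times = np.arange(states.shape[0]) * (stride * dt)
    return Trajectory(times=times, states=states, seed=seed, s=float(s), dt=dt)


def dorsal_rest_state(params: GRNParameters) -> np.ndarray:
    """Stable state of the signal-free system (dorsal identity): the default
    initial condition for tissue simulations."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fps = find_fixed_points(params, 0.0, n_starts=24, seed=0)
    stable = [fp for fp in fps if fp.stability == "stable"]
    if not stable:
        raise RuntimeError("no signal-free stable state found")
    # highest total expression (the expressing, not collapsed, state)
    return max(stable, key=lambda fp: fp.state.sum()).state


def classify_state(state, attractors, other_band: float = 0.12, scale=None) -> str:
    """Nearest-attractor assignment in log-concentration space.

    ``other_band`` is the half-width (as a fraction of the inter-attractor
    distance) of the tie region around the separatrix midpoint that is
    labelled "other".  With a single attractor its label is returned.
    """
    labelled = [fp for fp in attractors if fp.stability == "stable"]
    if not labelled:
        raise ValueError("attractor list carries no stable points")
    scale = np.ones_like(labelled[0].state) if scale is None else np.asarray(scale, float)
    eps = 1e-3
    z = np.log(np.asarray(state, float) / scale + eps)
    zs = [np.log(fp.state / scale + eps) for fp in labelled]
    d = np.array([np.linalg.norm(z - zi) for zi in zs])
    if len(labelled) == 1:
        return labelled[0].label
    order = np.argsort(d)
    i, j = order[0], order[1]
    dij = np.linalg.norm(zs[i] - zs[j])
    if abs(d[i] - d[j]) < other_band * dij:
        return "other"
    return labelled[i].label


def dorsal_branch_states(params: GRNParameters, profile: SignalProfile, positions):
    """Initial state per position: the attractor continued from the dorsal
    rest state as the signal rises ventrally (adiabatic gradient onset).

    Dorsal of the pMN-loss fold this is the pMN-branch state ("the system
    always adopts the pMN state in the bistable region"); ventral of the
    fold the branch has vanished and cells start on the remaining (p3)
    attractor.
    """
    from scipy import optimize

    positions = np.asarray(positions, float)
    order = np.argsort(positions)[::-1]          # dorsal -> ventral
    out = np.empty((len(positions), params.n_nodes))
    cur = dorsal_rest_state(params)
    sys_rhs = lambda x, s: rhs_deterministic(params, x, s)
    for k in order:
        s = profile(positions[k])
        sol = optimize.root(lambda x: sys_rhs(np.abs(x), s), cur, method="hybr")
        x = np.abs(sol.x)
        ok = sol.success and np.linalg.norm(sys_rhs(x, s)) < 1e-8
        if ok:
            from .model import jacobian as _jac, _classify

            ok = _classify(np.linalg.eigvals(_jac(params, x, s))) == "stable"
        if not ok:
            # branch lost (fold): relax deterministically to the remaining attractor
            from scipy.integrate import solve_ivp

            sol2 = solve_ivp(lambda t, y: sys_rhs(np.maximum(y, 0.0), s), (0.0, 400.0),
                             cur, rtol=1e-8, atol=1e-10)
            x = np.maximum(sol2.y[:, -1], 0.0)
        out[k] = x
        cur = x
    return out


def position_attractors(params: GRNParameters, profile: SignalProfile, positions):
    """Labelled fixed points at every position's (noise-free) signal level,
    computed by branch continuation from the ventral end."""
    positions = np.asarray(positions, float)
    svals = np.array([profile(r) for r in positions])
    # continuation over a monotone signal grid (positions sorted -> s decreasing)
    diagram = bifurcation_scan(params, svals[::-1], n_starts=10)
    return [diagram.branches[k] for k in range(len(svals))][::-1]


def simulate_tissue(
    params: GRNParameters,
    profile: SignalProfile | None = None,
    perturbation: MutantPerturbation | None = None,
    M: int = 40,
    cells_per_position: int = 60,
    duration: float = 50.0,
    dt: float = 0.02,
    seed: int = 0,
    genotype: str = "wt",
    positions=None,
    other_band: float = 0.12,
    x0=None,
) -> TissueSimulation:
    """Simulate independent cells along the dorsoventral axis.

    All cells start from the signal-free (dorsal) stable state and are
    integrated for ``duration`` hours at their local signal level.
    """
    if M < 2 or cells_per_position < 1:
        raise ValueError("need M >= 2 and cells_per_position >= 1")
    profile = profile or SignalProfile()
    if perturbation is not None:
        params = apply_mutant(params, perturbation)
    positions = np.linspace(0.0, 1.0, M) if positions is None else np.asarray(positions, float)
    if x0 is None:
        per_pos_x0 = dorsal_branch_states(params, profile, positions)
    else:
        per_pos_x0 = np.tile(np.asarray(x0, float), (len(positions), 1))

    rng = np.random.default_rng(_kernel_seed(seed, 1))
    cells = cells_per_position
    svals = np.empty(len(positions) * cells)
    for k, r in enumerate(positions):
        if profile.noise_sd > 0:
            svals[k * cells : (k + 1) * cells] = [profile(r, rng=rng) for _ in range(cells)]
        else:
            svals[k * cells : (k + 1) * cells] = profile(r)
    X0 = np.repeat(per_pos_x0, cells, axis=0)
    n_steps = int(round(duration / dt))
    end, ok = _kernels.em_endstates(
        X0, svals, n_steps, dt, params.omega, _kernel_seed(seed, 2), *_param_arrays(params)
    )
    if not ok:
        raise IntegrationError(f"state blow-up: time step dt={dt} too large")
    end = end.reshape(len(positions), cells, params.n_nodes)

    attractors = position_attractors(params, profile, positions)
    labels = np.empty((len(positions), cells), dtype=object)
    scale = np.maximum(params.scale, 1e-12)
    for k in range(len(positions)):
        atts = [fp for fp in attractors[k] if fp.stability == "stable"]
        if not atts:
            labels[k, :] = "other"
            continue
        for c in range(cells):
            labels[k, c] = classify_state(end[k, c], atts, other_band=other_band, scale=scale)
    return TissueSimulation(
        positions=positions,
        end_states=end,
        state_labels=labels,
        duration=duration,
        genotype=genotype,
        attractors=attractors,
    )


def tissue_boundary(tissue: TissueSimulation, band=(0.11, 0.89)) -> BoundaryResult:
    """Boundary position (50% p3 crossing) and width (extent of the band
    where the monotone-smoothed p3 fraction is inside ``band``)."""
    from sklearn.isotonic import IsotonicRegression

    frac = tissue.p3_fraction
    r = tissue.positions
    if frac.max() < 0.5 or frac.min() > 0.5:
        return BoundaryResult(False, None, None, reason="no 50% crossing of p3 occupancy")
    fit = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0).fit(r, frac)
    f = fit.predict(r)
    lo, hi = band

    def crossing(level):
        # f decreasing in r; first r where f <= level, linearly interpolated
        idx = np.flatnonzero(f <= level)
        if len(idx) == 0:
            return r[-1]
        k = idx[0]
        if k == 0:
            return r[0]
        f0, f1 = f[k - 1], f[k]
        if f0 == f1:
            return r[k]
        t = (f0 - level) / (f0 - f1)
        return r[k - 1] + t * (r[k] - r[k - 1])

    pos = crossing(0.5)
    r_hi = crossing(hi)   # ventral edge (fraction drops below hi)
    r_lo = crossing(lo)   # dorsal edge
    return BoundaryResult(True, float(pos), float(max(r_lo - r_hi, 0.0)))


def mfpt(
    params: GRNParameters, s: float, from_label: str = "pMN", to_label: str = "p3",
    n_cells: int = 200, t_max: float = 200.0, dt: float = 0.02, seed: int = 0,
    radius_frac: float = 0.1,
) -> FPTResult:
    """Fate jump time: ensemble first passage from one attractor into a ball
    (radius ``radius_frac`` of the scaled inter-attractor distance) around
    the other."""
    if n_cells < 1 or t_max <= 0:
        raise ValueError("need n_cells >= 1 and t_max > 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fps = find_fixed_points(params, s, n_starts=24, seed=0)
    by_label = {fp.label: fp for fp in fps if fp.stability == "stable"}
    if from_label not in by_label:
        return FPTResult(None, 1.0, None, np.empty(0), np.empty(0, bool),
                         reason=f"no {from_label} attractor at s={s}")
    if to_label not in by_label:
        return FPTResult(None, 1.0, None, np.empty(0), np.empty(0, bool),
                         reason=f"no-target: no {to_label} attractor at s={s}")
    src = by_label[from_label].state
    dst = by_label[to_label].state
    scale = np.maximum(params.scale, 1e-12)
    dist = np.linalg.norm((src - dst) / scale)
    radius2 = (radius_frac * dist) ** 2
    times, censored = _kernels.em_first_passage(
        src, float(s), dst, radius2, 1.0 / scale, n_cells, t_max, dt, params.omega,
        _kernel_seed(seed, 3), *_param_arrays(params),
    )
    unc = times[~censored]
    mean = float(unc.mean()) if len(unc) else None
    n_events = int((~censored).sum())
    mean_exp = float(times.sum() / n_events) if n_events else None
    return FPTResult(mean, float(censored.mean()), mean_exp, times, censored)


def expression_stats(samples, genes=None) -> NoiseStats:
    """Per-gene CV, covariance and total RMS variance over an ensemble.

    ``samples``: (cells, N) expression levels; ``genes``: column subset.
    rms_total = sqrt(trace(cov)), the root of the summed per-gene variances.
    """
    X = np.asarray(samples, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (cells >= 2, genes) array")
    if genes is not None:
        X = X[:, list(genes)]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    cv = np.full(X.shape[1], np.nan)
    ok = mean != 0
    cv[ok] = sd[ok] / mean[ok]
    if not np.all(ok):
        warnings.warn("zero-mean gene: CV undefined (NaN)")
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    return NoiseStats(
        genes=tuple(range(X.shape[1])) if genes is None else tuple(genes),
        cv_per_gene=cv,
        covariance=cov,
        rms_total=float(np.sqrt(np.trace(cov))),
    )
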