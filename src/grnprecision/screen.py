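"""Computational screen of three-node networks for boundary precision.

Random three-node Hill networks (all nine ordered interactions drawn from
{activation, repression, absent}, morphogen input into nodes 1 and 2) are
exposed to a graded input across a one-dimensional tissue.  A network is
accepted when it realises a bistable switch along the axis and converts
most of the tissue discontinuously within developmental time; accepted
networks are scored for

* boundary width (stochastic tissue simulation + occupancy band readout),
* minimum-action-path curvature at a reference offset dorsal to the fold,
* signal sensitivity (rate of separation of steady state and transition
  point per unit signal), and
* the effective contribution of the third node (the node without direct
  morphogen input), which classifies networks as effectively 2D or 3D.

Everything is deterministic given the screen seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import sde
from .action import (
    ActionError,
    curvature_metric,
    minimize_action,
    signal_sensitivity,
    third_node_contribution,
)
from .model import (
    FixedPoint,
    GRNParameters,
    NetworkSpec,
    SignalProfile,
    _classify,
    find_fixed_points,
    jacobian,
    rhs_deterministic,
)

_SIGN_CHAR = {1: "+", -1: "-", 0: "0"}


@dataclass
class ScreenConfig:
    n_samples: int = 1500
    params_per_topology: int = 4              # parameter draws per sampled topology
    alpha_range: tuple = (2.0, 5.0)           # log-uniform; narrow so expression
                                              # scales (and hence actions at fixed
                                              # omega) are comparable across draws
    K_range: tuple = (0.2, 2.5)               # log-uniform
    hill_choices: tuple = (2.0, 3.0, 4.0)
    K_s_range: tuple = (0.3, 2.0)             # log-uniform
    m_s: float = 2.0
    omega: float = 50.0
    duration: float = 50.0
    dt: float = 0.04
    M: int = 28
    cells_per_position: int = 24              # refined width readout
    accept_cells_per_position: int = 10       # coarse conversion check
    positions: tuple = (0.02, 0.8)
    width_threshold: float = 0.07             # "precise" boundary
    switch_fraction: float = 0.8              # conversion required across the axis
    reference_offset: float = 0.1             # MAP evaluated at fold + offset
    two_d_cutoff: float = 0.05                # third-node contribution below -> 2D
    map_points: int = 21
    signal: SignalProfile = field(default_factory=SignalProfile)
    seed: int = 0


def topology_id(spec: NetworkSpec) -> str:
    """Canonical id: 9 interaction signs (row-major, entry [i][j] = effect
    of node j on node i) plus the two input signs.  Nodes are
    distinguishable (inputs go to nodes 1 and 2), so no relabelling."""
    mat = "".join(_SIGN_CHAR[int(v)] for v in spec.sign.ravel())
    inp = "".join(_SIGN_CHAR[int(v)] for v in spec.signal_sign[:2])
    return f"{mat}|{inp}"


def sample_network(config: ScreenConfig, index: int):
    """Deterministic draw of (NetworkSpec, GRNParameters) for one index.

    Consecutive indices share a topology in blocks of
    ``params_per_topology`` (so per-topology precision fractions are
    estimable); parameters are drawn independently per index.
    """
    if index >= config.n_samples:
        raise IndexError("index beyond n_samples")
    t_index = index // max(config.params_per_topology, 1)
    t_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, t_index]))
    sign = t_rng.integers(-1, 2, size=(3, 3)).astype(np.int8)
    signal_sign = np.array([t_rng.choice([-1, 1]), t_rng.choice([-1, 1]), 0], dtype=np.int8)
    spec = NetworkSpec(node_names=("x1", "x2", "x3"), sign=sign, signal_sign=signal_sign)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))

    def logu(lo, hi, size=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    K = np.where(sign != 0, logu(*config.K_range, (3, 3)), 1.0)
    n = np.where(sign != 0, rng.choice(config.hill_choices, (3, 3)), 2.0)
    params = GRNParameters(
        spec=spec,
        alpha=logu(*config.alpha_range, 3),
        delta=np.ones(3),
        K=K,
        n=n,
        w=np.ones((3, 3)),
        K_s=np.where(signal_sign != 0, logu(*config.K_s_range, 3), 1.0),
        m_s=np.full(3, config.m_s),
        w_s=np.where(signal_sign != 0, 1.0, 0.0),
        w_b=np.where(signal_sign != 0, 0.0, 1.0),
        omega=config.omega,
    )
    return spec, params


# ---------------------------------------------------------------------------
# evaluation


def _occupancy_boundary(positions, frac):
    """(50% crossing, 11-89% band extent) of a monotone-smoothed occupancy
    profile; (None, None) when the profile does not cross 50%."""
    from sklearn.isotonic import IsotonicRegression

    f = IsotonicRegression(increasing=False, y_min=0, y_max=1).fit(positions, frac).predict(positions)
    if f[0] < 0.5 or f[-1] > 0.5:
        return None, None

    def crossing(level):
        idx = np.flatnonzero(f <= level)
        if len(idx) == 0:
            return positions[-1]
        k = idx[0]
        if k == 0 or f[k - 1] == f[k]:
            return positions[k]
        t = (f[k - 1] - level) / (f[k - 1] - f[k])
        return positions[k - 1] + t * (positions[k] - positions[k - 1])

    return crossing(0.5), max(crossing(0.11) - crossing(0.89), 0.0)


def _relax(params, x0, s, T=200.0, dt=0.05):
    return sde._kernels.relax(np.asarray(x0, float), float(s), int(T / dt), dt,
                              *sde._param_arrays(params))


def _dorsal_branch(params, profile, positions):
    """Continuation of the dorsal rest state ventralward.

    Returns (states, lost_at): per-position branch states and the index of
    the most dorsal position where the branch has vanished (fold), or None.
    """
    out = np.empty((len(positions), params.n_nodes))
    cur = _relax(params, 0.1 * params.scale + 1e-3, profile(positions[-1]))
    lost_at = None
    for k in range(len(positions) - 1, -1, -1):
        s = profile(positions[k])
        r = optimize.root(lambda x: rhs_deterministic(params, np.abs(x), s), cur, method="hybr")
        x = np.abs(r.x)
        ok = r.success and np.linalg.norm(rhs_deterministic(params, x, s)) < 1e-8
        if ok:
            ok = _classify(np.linalg.eigvals(jacobian(params, x, s))) == "stable"
        if not ok:
            lost_at = k
            # remaining ventral positions: relax to the surviving attractor
            for j in range(k, -1, -1):
                cur = _relax(params, cur, profile(positions[j]))
                out[j] = cur
            break
        out[k] = x
        cur = x
    return out, lost_at


def evaluate_network(spec: NetworkSpec, params: GRNParameters, config: ScreenConfig,
                     index: int = 0) -> dict:
    """Full evaluation of one sampled network; never raises on numerical
    failure (the record carries a rejection reason instead)."""
    rec = {
        "index": index,
        "topology_id": topology_id(spec),
        "accepted": False,
        "reason": "",
        "boundary_width": np.nan,
        "boundary_position": np.nan,
        "curvature": np.nan,
        "signal_sensitivity": np.nan,
        "third_node_contribution": np.nan,
        "effective_dim": "",
    }
    profile = config.signal
    positions = np.linspace(config.positions[0], config.positions[1], config.M)
    try:
        # coarse pre-screen: most draws are monostable along the whole axis
        coarse, lost_c = _dorsal_branch(params, profile, positions[::2])
        if lost_c is None:
            rec["reason"] = "no bistable switch (dorsal branch continues everywhere)"
            return rec
        branch, lost_at = _dorsal_branch(params, profile, positions)
    except Exception as e:  # noqa: BLE001 - screen must not crash
        rec["reason"] = f"continuation failure: {type(e).__name__}"
        return rec
    if lost_at is None:
        rec["reason"] = "no bistable switch (dorsal branch continues everywhere)"
        return rec
    r_fold = positions[lost_at]
    scale = np.maximum(params.scale, 1e-12)
    ventral_state = branch[0]
    dorsal_state = branch[-1]
    if np.linalg.norm((ventral_state - dorsal_state) / scale) < 0.3:
        rec["reason"] = "no bistable switch (end states indistinct)"
        return rec

    # stochastic tissue: cells start on the dorsal-continued branch
    try:
        n_steps = int(round(config.duration / config.dt))
        cells = config.accept_cells_per_position
        X0 = np.repeat(branch, cells, axis=0)
        svals = np.repeat([profile(r) for r in positions], cells)
        end, ok = sde._kernels.em_endstates(
            X0, np.asarray(svals, float), n_steps, config.dt, params.omega,
            sde._kernel_seed(config.seed, 7, index), *sde._param_arrays(params),
        )
        if not ok:
            rec["reason"] = "SDE blow-up"
            return rec
        end = end.reshape(config.M, cells, 3)
    except Exception as e:  # noqa: BLE001
        rec["reason"] = f"simulation failure: {type(e).__name__}"
        return rec

    # occupancy of the ventral end-state
    dv = np.linalg.norm((end - ventral_state) / scale, axis=2)
    dd = np.linalg.norm((end - dorsal_state) / scale, axis=2)
    frac_v = (dv < dd).mean(axis=1)
    need = config.switch_fraction
    if not (frac_v[0] >= (1 + need) / 2 and frac_v[-1] <= (1 - need) / 2):
        rec["reason"] = "incomplete switch across tissue"
        return rec
    pos_w, width = _occupancy_boundary(positions, frac_v)
    # refine the width on a fine local grid around the fold (the global
    # grid spacing would otherwise quantise sharp boundaries)
    try:
        local = np.linspace(max(r_fold - 0.06, 0.01), min(r_fold + 0.34, 0.95), 72)
        branch_l, _ = _dorsal_branch(params, profile, local)
        cells_l = config.cells_per_position
        X0l = np.repeat(branch_l, cells_l, axis=0)
        svals_l = np.repeat([profile(r) for r in local], cells_l)
        end_l, ok = sde._kernels.em_endstates(
            X0l, np.asarray(svals_l, float), n_steps, config.dt, params.omega,
            sde._kernel_seed(config.seed, 8, index), *sde._param_arrays(params),
        )
        if ok:
            end_l = end_l.reshape(len(local), cells_l, 3)
            dvl = np.linalg.norm((end_l - ventral_state) / scale, axis=2)
            ddl = np.linalg.norm((end_l - dorsal_state) / scale, axis=2)
            fl = (dvl < ddl).mean(axis=1)
            pos2, width2 = _occupancy_boundary(local, fl)
            if pos2 is not None:
                pos_w, width = pos2, width2
    except Exception:  # noqa: BLE001 - refinement is best-effort
        pass
    if pos_w is None:
        rec["reason"] = "no occupancy crossing"
        return rec
    rec["boundary_position"] = float(pos_w)
    rec["boundary_width"] = float(width)

    # path metrics at the reference offset dorsal to the fold
    r_star = r_fold + config.reference_offset
    if r_star > positions[-1]:
        rec["reason"] = "fold too close to dorsal end for path metrics"
        return rec
    s_star = profile(r_star)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fps = find_fixed_points(params, s_star, n_starts=20, seed=0)
        stable = [fp for fp in fps if fp.stability == "stable"]
        saddles = [fp for fp in fps if fp.stability == "saddle"]
        if len(stable) < 2 or not saddles:
            rec["reason"] = "bistability lost at reference position"
            return rec
        # source = the branch state cells occupy; saddle nearest to it
        k_star = int(np.argmin(np.abs(positions - r_star)))
        src_state = branch[k_star]
        src = min(stable, key=lambda fp: np.linalg.norm((fp.state - src_state) / scale))
        sad = min(saddles, key=lambda fp: np.linalg.norm((fp.state - src.state) / scale))
        path = minimize_action(params, s_star, src, sad, P=config.map_points,
                               tol=1e-5, maxiter=200, max_outer=3)
        rec["curvature"] = float(curvature_metric(path)[0])
        rec["third_node_contribution"] = float(third_node_contribution(path, node_index=2))
        ds = 0.05 * s_star
        rec["signal_sensitivity"] = float(
            signal_sensitivity(params, s_star, ds, stable_label=None, ref_state=src.state)
        )
    except (ActionError, RuntimeError, np.linalg.LinAlgError) as e:
        rec["reason"] = f"path metrics failed: {type(e).__name__}"
        for key in ("curvature", "signal_sensitivity", "third_node_contribution"):
            rec[key] = np.nan
        return rec
    rec["accepted"] = True
    rec["effective_dim"] = "2D" if rec["third_node_contribution"] < config.two_d_cutoff else "3D"
    return rec


@dataclass
class ScreenResult:
    records: pd.DataFrame
    config: ScreenConfig
    summary: dict = field(default_factory=dict)

    @property
    def accepted(self) -> pd.DataFrame:
        if self.records.empty:
            return self.records
        return self.records[self.records["accepted"]]


def run_screen(config: ScreenConfig, progress: bool = False) -> ScreenResult:
    """Evaluate all sampled networks; fully reproducible given the seed."""
    rows = []
    for i in range(config.n_samples):
        spec, params = sample_network(config, i)
        rows.append(evaluate_network(spec, params, config, index=i))
        if progress and (i + 1) % 200 == 0:
            n_acc = sum(r["accepted"] for r in rows)
            print(f"  screened {i+1}/{config.n_samples} ({n_acc} accepted)", flush=True)
    records = pd.DataFrame(rows)
    result = ScreenResult(records=records, config=config)
    acc = result.accepted
    summary = {"n_samples": config.n_samples, "n_accepted": int(len(acc))}
    if len(acc) >= 3:
        from scipy.stats import spearmanr

        summary["spearman_width_curvature"] = float(
            spearmanr(acc["boundary_width"], acc["curvature"]).statistic
        )
        summary["spearman_width_sensitivity"] = float(
            spearmanr(acc["boundary_width"], acc["signal_sensitivity"]).statistic
        )
        for dim in ("2D", "3D"):
            sel = acc[acc["effective_dim"] == dim]["boundary_width"]
            if len(sel):
                summary[f"width_q25_{dim}"] = float(sel.quantile(0.25))
                summary[f"width_median_{dim}"] = float(sel.median())
                summary[f"n_{dim}"] = int(len(sel))
    result.summary = summary
    return result


def rank_topologies(result: ScreenResult, width_threshold: float | None = None,
                    min_count: int = 3) -> pd.DataFrame:
    """Topology table ordered by the fraction of accepted parameter sets
    producing a precise (width < threshold) boundary.

    Motif columns annotate inhibition from node 2 to node 3
    (``x2_represses_x3``) and repression from node 3 to node 2
    (``x3_represses_x2``); sign entry [i][j] is the effect of j on i.
    """
    acc = result.accepted
    if acc.empty:
        return pd.DataFrame(columns=["topology_id", "count", "fraction_precise"])
    th = width_threshold if width_threshold is not None else result.config.width_threshold
    rows = []
    for tid, grp in acc.groupby("topology_id"):
        mat = tid.split("|")[0]
        rows.append({
            "topology_id": tid,
            "count": len(grp),
            "fraction_precise": float((grp["boundary_width"] < th).mean()),
            "median_width": float(grp["boundary_width"].median()),
            "x2_represses_x3": mat[7] == "-",   # entry [2][1]: effect of node2 on node3
            "x3_represses_x2": mat[5] == "-",   # entry [1][2]: effect of node3 on node2
        })
    out = pd.DataFrame(rows)
    out = out[out["count"] >= min_count]
    return out.sort_values(["fraction_precise", "count"], ascending=[False, False]).reset_index(drop=True)


def evaluate_wildtype_network(config: ScreenConfig | None = None) -> dict:
    """The packaged neural-tube network pushed through the screen pipeline.

    Node order is rearranged to the screen convention (inputs on nodes 1
    and 2): x1 = Nkx2.2, x2 = Olig2, x3 = Pax6.
    """
    from .config import default_model

    cfg = config or ScreenConfig()
    params, profile, _ = default_model("wt")
    order = [params.index("Nkx2.2"), params.index("Olig2"), params.index("Pax6")]
    P = np.ix_(order, order)
    spec = NetworkSpec(
        node_names=tuple(params.spec.node_names[i] for i in order),
        sign=params.spec.sign[P],
        signal_sign=params.spec.signal_sign[order],
    )
    re_params = GRNParameters(
        spec=spec,
        alpha=params.alpha[order], delta=params.delta[order],
        K=params.K[P], n=params.n[P], w=params.w[P],
        K_s=params.K_s[order], m_s=params.m_s[order],
        w_s=params.w_s[order], w_b=params.w_b[order],
        omega=params.omega,
    )
    cfg2 = ScreenConfig(**{**cfg.__dict__, "signal": profile})
    rec = evaluate_network(spec, re_params, cfg2, index=10**6)
    rec["index"] = -1
    return rec
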