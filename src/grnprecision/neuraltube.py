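"""Genotype-level analyses of the packaged neural-tube model.

Convenience layer over the model / SDE / action modules that phrases the
standard comparisons of the study: boundary position and width per
genotype, the pMN-loss bifurcation position, effective energy barriers and
path geometry at matched fractional distances from the bifurcation,
expression noise in retained pMN cells, and fate jump times across the
heterogeneous boundary region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import sde
from .action import curvature_metric, minimize_action
from .config import default_model
from .model import find_fixed_points

GENOTYPES = ("wt", "o2e33", "pax6ko")


def load_genotype(genotype: str = "wt", omega: float | None = None):
    params, profile, cfg = default_model(genotype)
    if omega is not None:
        params = replace(params, omega=float(omega))
    return params, profile, cfg


def fold_position(params, profile, r_min=0.02, r_max=0.68, n_grid=120):
    """Position of the pMN-loss fold (ventral limit of pMN stability) and
    the dorsal end of the bistable band, as axis fractions."""
    rr = np.linspace(r_min, r_max, n_grid)
    from .model import bifurcation_scan

    ss = np.array([profile(r) for r in rr])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = bifurcation_scan(params, ss[::-1], n_starts=8)
    branches = d.branches[::-1]
    has2 = np.array([
        sum(fp.stability == "stable" for fp in b) >= 2
        and any(fp.stability == "saddle" for fp in b)
        for b in branches
    ])
    idx = np.flatnonzero(has2)
    if len(idx) == 0:
        raise RuntimeError("no bistable band found on the position grid")
    return float(rr[idx[0]]), float(rr[idx[-1]])


def _pmn_and_saddle(params, s):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fps = find_fixed_points(params, s, n_starts=30, seed=0)
    pmn = [f for f in fps if f.label == "pMN"]
    sad = [f for f in fps if f.stability == "saddle"]
    p3 = [f for f in fps if f.label == "p3"]
    if not pmn or not sad:
        raise RuntimeError(f"pMN attractor or transition point missing at s={s}")
    return pmn[0], sad[0], (p3[0] if p3 else None)


@dataclass
class BarrierResult:
    genotype: str
    r_fold: float
    offset: float
    barrier: float
    curvature: float
    third_node_contribution: float
    path: object


def barrier_at_offset(genotype: str, offset: float = 0.1, P: int = 27, tol: float = 1e-7):
    """Effective energy barrier (cumulative action at the transition point)
    at a fractional position ``offset`` dorsal to the bifurcation point."""
    from .action import third_node_contribution

    params, profile, _ = load_genotype(genotype)
    r_fold, r_end = fold_position(params, profile)
    r_star = r_fold + offset
    if r_star > r_end:
        raise RuntimeError(f"{genotype}: offset {offset} leaves the bistable band")
    s = profile(r_star)
    pmn, sad, p3 = _pmn_and_saddle(params, s)
    path = minimize_action(params, s, pmn, sad, target=p3, P=P, tol=tol)
    pax6_idx = params.index("Pax6")
    return BarrierResult(
        genotype=genotype,
        r_fold=r_fold,
        offset=offset,
        barrier=path.total_action,
        curvature=curvature_metric(path)[0],
        third_node_contribution=third_node_contribution(path, node_index=pax6_idx),
        path=path,
    )


def boundary_replicates(genotype: str, n_replicates: int = 10, seed: int = 0,
                        M: int = 56, cells_per_position: int = 40,
                        positions=(0.1, 0.68), duration: float = 50.0, dt: float = 0.02):
    """Boundary position and width over independent replicate tissues."""
    params, profile, _ = load_genotype(genotype)
    pos_grid = np.linspace(positions[0], positions[1], M)
    widths, locs = [], []
    for k in range(n_replicates):
        tis = sde.simulate_tissue(
            params, profile, M=M, cells_per_position=cells_per_position,
            duration=duration, dt=dt, seed=seed * 1000 + k, genotype=genotype,
            positions=pos_grid,
        )
        b = sde.tissue_boundary(tis)
        if b.defined:
            widths.append(b.width)
            locs.append(b.position)
    return np.array(locs), np.array(widths)


def pmn_noise_stats(genotype: str, offsets=(0.06, 0.1, 0.14), n_cells: int = 120,
                    duration: float = 30.0, dt: float = 0.02, seed: int = 0):
    """Relative (mean-normalised) fluctuation statistics of Olig2 and Pax6
    in cells that remain in the pMN state, pooled over positions at matched
    fractional distances from each genotype's bifurcation point.

    Returns (cv_olig2, cv_pax6, rms_total) where rms_total is the square
    root of the trace of the covariance of relative levels.
    """
    params, profile, _ = load_genotype(genotype)
    r_fold, r_end = fold_position(params, profile)
    io, ip = params.index("Olig2"), params.index("Pax6")
    scale = np.maximum(params.scale, 1e-12)
    samples = []
    for j, off in enumerate(offsets):
        r = min(r_fold + off, r_end)
        s = profile(r)
        pmn, sad, _ = _pmn_and_saddle(params, s)
        X0 = np.tile(pmn.state, (n_cells, 1))
        end, ok = sde._kernels.em_endstates(
            X0, np.full(n_cells, s), int(round(duration / dt)), dt, params.omega,
            sde._kernel_seed(seed, 40 + j), *sde._param_arrays(params),
        )
        if not ok:
            raise sde.IntegrationError("state blow-up in noise-stats ensemble")
        # keep cells still in the pMN basin (scaled distance to pMN < to saddle)
        d_pmn = np.linalg.norm((end - pmn.state) / scale, axis=1)
        d_sad = np.linalg.norm((end - sad.state) / scale, axis=1)
        keep = d_pmn < d_sad
        # relative fluctuations around the local mean; a deleted gene
        # (zero mean) contributes zero relative fluctuation
        lv = end[keep][:, [io, ip]]
        if keep.sum() < 10:
            continue
        mu = lv.mean(axis=0)
        rel = np.zeros_like(lv)
        pos = mu > 1e-9
        rel[:, pos] = lv[:, pos] / mu[pos]
        samples.append(rel)
    X = np.vstack(samples)
    return sde.expression_stats(X)


def pmn_relative_noise(genotype: str, **kw):
    """(cv_olig2, cv_pax6, rms_total) of relative Olig2/Pax6 fluctuations
    in retained pMN cells (see :func:`pmn_noise_stats`)."""
    stats = pmn_noise_stats(genotype, **kw)
    cv_o = float(np.sqrt(stats.covariance[0, 0]))
    cv_p = float(np.sqrt(stats.covariance[1, 1]))
    return cv_o, cv_p, stats.rms_total


def fate_jump_profile(genotype: str, offsets=(0.02, 0.05, 0.08, 0.12), n_cells: int = 150,
                      t_max: float = 400.0, dt: float = 0.02, seed: int = 0):
    """Mean pMN->p3 fate jump time at fractional distances from the fold."""
    params, profile, _ = load_genotype(genotype)
    r_fold, r_end = fold_position(params, profile)
    out = []
    for off in offsets:
        r = r_fold + off
        if r > r_end:
            out.append((off, None, 1.0))
            continue
        res = sde.mfpt(params, profile(r), n_cells=n_cells, t_max=t_max, dt=dt, seed=seed)
        out.append((off, res.mean_exposure, res.censored_fraction))
    return out


def heterogeneity_jump_time(n_cells: int = 200, seed: int = 0, duration: float = 50.0,
                            M: int = 48, cells_per_position: int = 30,
                            t_max: float = 400.0, dt: float = 0.02, genotype: str = "wt"):
    """Mean fate jump time inside the heterogeneous boundary region.

    A tissue simulation locates positions whose p3 conversion fraction at
    developmental time lies strictly inside (0.05, 0.95); the jump time is
    then measured by ensemble first passage at the ventral-most such
    position (the heart of the heterogeneous region, where spontaneous
    transitions are frequent but incomplete).
    """
    params, profile, _ = load_genotype(genotype)
    pos_grid = np.linspace(0.1, 0.68, M)
    tis = sde.simulate_tissue(params, profile, M=M, cells_per_position=cells_per_position,
                              duration=duration, dt=dt, seed=seed, genotype=genotype,
                              positions=pos_grid)
    frac = tis.p3_fraction
    band = np.flatnonzero((frac > 0.05) & (frac < 0.95))
    if len(band) == 0:
        raise RuntimeError("no heterogeneous positions found")
    r_star = float(pos_grid[band[0]])
    res = sde.mfpt(params, profile(r_star), n_cells=n_cells, t_max=t_max, dt=dt, seed=seed)
    return res, r_star, frac[band[0]]
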