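"""Image-quantification statistics: normalisation, cell typing and
Gaussian-process boundary measurement on per-cell intensity tables.

Input is a table of nuclei from a neural-tube cross-section (coordinates in
um plus DAPI / Nkx2.2 / Olig2 / Pax6 mean intensities) together with
ventral and dorsal reference points per embryo.  The pipeline

1. aligns sections (ventral pole at the origin, dorsoventral axis vertical),
2. removes low-DAPI artefacts and floors dim outliers per channel,
3. anchors intensity quantiles so embryos are comparable
   (Nkx2.2/Olig2: min -> 0 and 40% quantile -> 0.08; Pax6: 60% -> 0.6),
4. classifies cells into floor plate / p3 / pMN / Irx3+ / other from
   Nkx2.2, Olig2 and dorsoventral position (Pax6 deliberately unused so
   Pax6 mutants are scored without bias),
5. fits a binary Gaussian-process classifier (squared-exponential kernel
   with independent x/y length scales, logistic link, Laplace posterior)
   for the probability of the p3 type, and
6. reads off the boundary: position = mean dorsoventral location of the
   50% probability contour; width = mean extent of the 11-89% band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

CHANNELS = ("nkx22", "olig2", "pax6")
REQUIRED_COLUMNS = ("embryo_id", "x_um", "y_um", "dapi") + CHANNELS

DEFAULT_BAND = (0.11, 0.89)


class PreprocessError(ValueError):
    pass


@dataclass
class NormConfig:
    dapi_sd_cut: float = 2.0          # drop cells with DAPI < mean - cut*sd
    channel_sd_cut: float = 2.0       # floor dim intensities per channel
    floor_value: float = 0.0
    nkx_olig_quantile: float = 0.40
    nkx_olig_anchor: float = 0.08
    pax6_quantile: float = 0.60
    pax6_anchor: float = 0.60
    min_cells: int = 50


@dataclass
class CellTypeThresholds:
    nkx_high: float = 0.3
    olig2_high: float = 0.3
    floor_plate_max_frac: float = 0.06   # DV windows as fractions of tissue length
    p3_max_frac: float = 0.55
    pmn_max_frac: float = 0.75
    pax6_high: float = 0.45


@dataclass
class BoundaryEstimate:
    defined: bool
    position_um: float | None
    width_um: float | None
    band: tuple = DEFAULT_BAND
    n_columns: int = 0
    hyperparameters: dict = field(default_factory=dict)
    reason: str = ""


def read_cell_table(cells_csv, refs_csv):
    """Load a per-cell intensity table and its reference points from CSV.

    Expected columns: cells — embryo_id, x_um, y_um, dapi, nkx22, olig2,
    pax6; refs — embryo_id, ventral_x, ventral_y, dorsal_x, dorsal_y.
    """
    table = pd.read_csv(cells_csv)
    refs = pd.read_csv(refs_csv)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise PreprocessError(f"cell table missing columns: {missing}")
    need = ["embryo_id", "ventral_x", "ventral_y", "dorsal_x", "dorsal_y"]
    missing = [c for c in need if c not in refs.columns]
    if missing:
        raise PreprocessError(f"reference table missing columns: {missing}")
    return table, refs


def _refs_for(refs: pd.DataFrame, embryo_id) -> pd.Series:
    sel = refs[refs["embryo_id"] == embryo_id]
    if len(sel) != 1:
        raise PreprocessError(f"embryo {embryo_id!r}: need exactly one reference row")
    return sel.iloc[0]


def preprocess(table: pd.DataFrame, refs: pd.DataFrame, config: NormConfig | None = None) -> pd.DataFrame:
    """Alignment, artefact removal and per-embryo intensity normalisation.

    Returns a new table; the input is not modified.  Raises
    :class:`PreprocessError` naming the embryo if fewer than
    ``config.min_cells`` cells survive filtering.
    """
    cfg = config or NormConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise PreprocessError(f"missing columns: {missing}")
    out = []
    for eid, df in table.groupby("embryo_id", sort=False):
        df = df.copy()
        ref = _refs_for(refs, eid)
        # (1) align: ventral pole -> origin, dorsoventral axis -> +y
        vx, vy = float(ref["ventral_x"]), float(ref["ventral_y"])
        dx, dy = float(ref["dorsal_x"]) - vx, float(ref["dorsal_y"]) - vy
        theta = np.arctan2(dx, dy)  # rotation taking (dx,dy) onto +y
        c, s = np.cos(theta), np.sin(theta)
        X = df["x_um"].to_numpy() - vx
        Y = df["y_um"].to_numpy() - vy
        df["x_um"] = c * X - s * Y
        df["y_um"] = s * X + c * Y
        # (2) low-DAPI artefact removal
        mu, sd = df["dapi"].mean(), df["dapi"].std(ddof=1)
        df = df[df["dapi"] >= mu - cfg.dapi_sd_cut * sd]
        if len(df) < cfg.min_cells:
            raise PreprocessError(f"embryo {eid!r}: only {len(df)} cells after DAPI filter")
        # (3) floor dim outliers per channel
        for ch in CHANNELS:
            mu, sd = df[ch].mean(), df[ch].std(ddof=1)
            df.loc[df[ch] < mu - cfg.channel_sd_cut * sd, ch] = cfg.floor_value
        # (4) Nkx2.2 / Olig2: min -> 0, q40 -> anchor
        for ch in ("nkx22", "olig2"):
            lo = df[ch].min()
            q = df[ch].quantile(cfg.nkx_olig_quantile)
            if q - lo <= 0:
                raise PreprocessError(f"embryo {eid!r}: degenerate {ch} distribution")
            df[ch] = (df[ch] - lo) * (cfg.nkx_olig_anchor / (q - lo))
        # (5) Pax6: q60 -> anchor
        q = df["pax6"].quantile(cfg.pax6_quantile)
        if q <= 0:
            raise PreprocessError(f"embryo {eid!r}: degenerate pax6 distribution")
        df["pax6"] = df["pax6"] * (cfg.pax6_anchor / q)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def classify_cells(
    table: pd.DataFrame,
    thresholds: CellTypeThresholds | None = None,
    use_pax6: bool = False,
) -> pd.Series:
    """Five-type cell classification from Nkx2.2, Olig2 and DV position.

    Returns a Series of labels in {floor_plate, p3, pMN, Irx3pos, other}
    aligned with ``table``.  Pax6 enters only when ``use_pax6`` is set (the
    pMN/Irx3+ boundary task); the p3/pMN calls never use it.
    """
    th = thresholds or CellTypeThresholds()
    for v in (th.nkx_high, th.olig2_high):
        if not 0 < v < 1:
            raise ValueError("intensity thresholds must lie in the normalised (0,1) range")
    labels = np.full(len(table), "other", dtype=object)
    y = table["y_um"].to_numpy()
    L = float(y.max()) if len(y) else 1.0
    nkx = table["nkx22"].to_numpy()
    olig = table["olig2"].to_numpy()
    yfrac = y / max(L, 1e-9)

    nkx_hi = nkx >= th.nkx_high
    olig_hi = olig >= th.olig2_high
    p3 = nkx_hi & (~olig_hi | (nkx >= olig)) & (yfrac <= th.p3_max_frac)
    pmn = olig_hi & ~p3 & (yfrac <= th.pmn_max_frac)
    neither = ~nkx_hi & ~olig_hi
    fp = neither & (yfrac <= th.floor_plate_max_frac)
    irx = neither & (yfrac > th.pmn_max_frac)
    if use_pax6:
        pax_hi = table["pax6"].to_numpy() >= th.pax6_high
        irx = irx | (neither & pax_hi & (yfrac > th.p3_max_frac))
    labels[p3] = "p3"
    labels[pmn] = "pMN"
    labels[fp] = "floor_plate"
    labels[irx] = "Irx3pos"
    return pd.Series(labels, index=table.index, name="cell_type")


class ProbabilityField:
    """Callable p3-probability field fitted by a GP classifier.

    ``mode="mean"`` (default) applies the logistic transfer to the GP
    posterior-mean latent, which keeps the probability profile calibrated
    to the local class mixture; ``mode="averaged"`` integrates the logistic
    over the Laplace posterior (scikit-learn's ``predict_proba``), which is
    smoother but blurs sharp boundaries.
    """

    def __init__(self, clf, bbox, hyperparameters, mode: str = "mean"):
        self._clf = clf
        self.bbox = bbox          # (xmin, xmax, ymin, ymax)
        self.hyperparameters = hyperparameters
        self.mode = mode

    def __call__(self, x, y):
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        X = np.column_stack([x, y])
        if self.mode == "averaged":
            return self._clf.predict_proba(X)[:, 1]
        est = self._clf.base_estimator_
        f = est.kernel_(X, est.X_train_) @ (est.y_train_ - est.pi_)
        return 1.0 / (1.0 + np.exp(-f))


def fit_boundary_classifier(
    table: pd.DataFrame,
    calls: pd.Series,
    target_type: str = "p3",
    restrict_to: tuple = ("p3", "pMN"),
    length_scale0: tuple = (50.0, 3.0),
    max_cells: int = 700,
    min_cells_per_class: int = 10,
    seed: int = 0,
    mode: str = "mean",
) -> ProbabilityField:
    """Binary GP classifier (target type vs rest) over (x, y) positions.

    Constant-mean GP, squared-exponential kernel with automatic relevance
    determination (separate x and y length scales), logistic link, Laplace
    approximate posterior; hyperparameters by marginal-likelihood
    maximisation.  By default only the two classes flanking the boundary
    of interest are used (``restrict_to``), which keeps the field monotone
    across the interface; cells beyond ``max_cells`` are deterministically
    subsampled for tractability.
    """
    if restrict_to:
        keep = calls.isin(restrict_to).to_numpy()
        table = table.loc[keep]
        calls = calls.loc[keep]
    y01 = (calls == target_type).to_numpy().astype(int)
    n1 = int(y01.sum())
    n0 = len(y01) - n1
    if n1 < min_cells_per_class or n0 < min_cells_per_class:
        raise ValueError(
            f"need >= {min_cells_per_class} cells per class (have {n1} {target_type}, {n0} rest)"
        )
    X = table[["x_um", "y_um"]].to_numpy()
    if len(X) > max_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), size=max_cells, replace=False)
        idx.sort()
        X, y01 = X[idx], y01[idx]
    kernel = ConstantKernel(9.0, (0.1, 1e4)) * RBF(
        list(length_scale0), length_scale_bounds=(2.0, 300.0)
    )
    clf = GaussianProcessClassifier(kernel=kernel, n_restarts_optimizer=0, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y01)
    k = clf.kernel_
    hp = {
        "amplitude": float(np.sqrt(k.k1.constant_value)),
        "length_scale_x": float(k.k2.length_scale[0]),
        "length_scale_y": float(k.k2.length_scale[1]),
        "log_marginal_likelihood": float(clf.log_marginal_likelihood_value_),
    }
    bbox = (X[:, 0].min(), X[:, 0].max(), X[:, 1].min(), X[:, 1].max())
    return ProbabilityField(clf, bbox, hp, mode=mode)


def boundary_width_position(
    field,
    bbox=None,
    band=DEFAULT_BAND,
    column_spacing: float = 2.0,
    row_spacing: float = 1.0,
) -> BoundaryEstimate:
    """Geometric boundary readout from a probability field.

    Per left-right column the dorsoventral 50% crossing and the extent of
    the probability band around it are measured on an evaluation grid;
    position and width are their means over columns that cross.
    """
    if bbox is None:
        bbox = getattr(field, "bbox", None)
        if bbox is None:
            raise ValueError("supply bbox when the field does not carry one")
    xmin, xmax, ymin, ymax = bbox
    xs = np.arange(xmin, xmax + 1e-9, column_spacing)
    ys = np.arange(ymin, ymax + 1e-9, row_spacing)
    if len(xs) < 1 or len(ys) < 3:
        return BoundaryEstimate(False, None, None, band, reason="degenerate bounding box")
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    P = np.asarray(field(XX.ravel(), YY.ravel()), float).reshape(len(xs), len(ys))
    lo, hi = band
    positions, widths = [], []
    for k in range(len(xs)):
        p = P[k]
        cross = _crossings(ys, p, 0.5)
        if cross is None:
            continue
        y_lo = _crossings(ys, p, hi)
        y_hi = _crossings(ys, p, lo)
        ventral = y_lo if y_lo is not None else ys[0]
        dorsal = y_hi if y_hi is not None else ys[-1]
        lo_edge, hi_edge = sorted((ventral, dorsal))
        positions.append(cross)
        widths.append(hi_edge - lo_edge)
    if not positions:
        return BoundaryEstimate(False, None, None, band,
                                reason="probability band absent on evaluation grid")
    hp = getattr(field, "hyperparameters", {})
    return BoundaryEstimate(True, float(np.mean(positions)), float(np.mean(widths)),
                            band, n_columns=len(positions), hyperparameters=dict(hp))


def _crossings(ys, p, level):
    """Dorsoventral location where p crosses ``level`` (mean of all
    sign-change interpolations; None if no crossing)."""
    d = p - level
    sgn = np.sign(d)
    idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
    hits = []
    for k in idx:
        t = d[k] / (d[k] - d[k + 1])
        hits.append(ys[k] + t * (ys[k + 1] - ys[k]))
    exact = np.flatnonzero(d == 0)
    hits.extend(ys[exact])
    if not hits:
        return None
    return float(np.mean(hits))


def tf_levels_boundary(
    table: pd.DataFrame,
    calls: pd.Series,
    field,
    band=DEFAULT_BAND,
    olig2_positive: float = 0.3,
) -> pd.DataFrame:
    """Normalised (Olig2, Pax6) levels of Olig2+ cells inside the boundary
    region (cells whose local p3 probability falls in the band)."""
    p = np.asarray(field(table["x_um"].to_numpy(), table["y_um"].to_numpy()), float)
    lo, hi = band
    sel = (p >= lo) & (p <= hi) & (table["olig2"].to_numpy() >= olig2_positive)
    out = table.loc[sel, ["embryo_id", "x_um", "y_um", "olig2", "pax6"]].copy()
    out["p3_probability"] = p[sel]
    if out.empty:
        warnings.warn("no Olig2+ cells inside the boundary region")
    return out.reset_index(drop=True)


def variance_stats(
    table: pd.DataFrame,
    calls: pd.Series,
    field,
    band=DEFAULT_BAND,
    genes=("olig2", "pax6"),
):
    """Covariance of normalised (Olig2, Pax6) in pMN cells outside the
    boundary region, and rms_total = sqrt(trace(cov))."""
    from .sde import expression_stats

    p = np.asarray(field(table["x_um"].to_numpy(), table["y_um"].to_numpy()), float)
    lo, hi = band
    outside = (p < lo) | (p > hi)
    sel = outside & (calls.to_numpy() == "pMN")
    X = table.loc[sel, list(genes)].to_numpy()
    if len(X) < 2:
        return None
    return expression_stats(X)
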