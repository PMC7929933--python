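"""Synthetic data generators: embryo-section cell tables with known boundary
truth, benchmark dynamical systems with closed-form escape properties, and
reduced-scale model-tissue fixtures.

Every generator is a pure function of (config, seed), so all downstream
stages are testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import DynamicalSystem, FixedPoint, GRNParameters, NetworkSpec

#: 11-89% band extent of a logistic profile per unit of its scale parameter:
#: 2 * ln(0.89 / 0.11)
LOGISTIC_BAND_FACTOR = float(2.0 * np.log(0.89 / 0.11))


# ---------------------------------------------------------------------------
# synthetic embryo sections


@dataclass(frozen=True)
class SyntheticEmbryoConfig:
    """Emulates a quantified E9.5 neural-tube cross-section.

    Domains are stacked ventral to dorsal (floor plate, p3, pMN, Irx3+)
    with span fractions summing to 1.  ``boundary_width_um`` is the true
    p3/pMN boundary width defined as the 11-89% extent of the logistic
    type-mixing profile.  Channel intensities are log-normal per cell type;
    a fraction of cells are injected low-DAPI artefacts (mis-identified
    nuclei).  The observable table never contains the truth columns.
    """

    n_cells: int = 1000
    length_um: float = 300.0          # dorsoventral extent; E9.5 window 250-350
    width_um: float = 100.0           # left-right extent of the hemisection
    spans: tuple = (0.06, 0.16, 0.24, 0.54)   # floor_plate, p3, pMN, Irx3pos
    boundary_width_um: float = 20.0
    intensity_means: dict = field(default_factory=lambda: {
        "floor_plate": {"nkx22": 0.05, "olig2": 0.05, "pax6": 0.06},
        "p3":          {"nkx22": 0.85, "olig2": 0.07, "pax6": 0.10},
        "pMN":         {"nkx22": 0.06, "olig2": 0.80, "pax6": 0.55},
        "Irx3pos":     {"nkx22": 0.05, "olig2": 0.06, "pax6": 0.80},
    })
    intensity_cv: float = 0.30
    dapi_mean: float = 1.0
    dapi_sd: float = 0.10
    artefact_fraction: float = 0.05
    artefact_dapi_shift: float = 3.5  # in dapi_sd units below the mean
    embryo_gain_sd: float = 0.15      # per-embryo multiplicative batch factor
    section_offset_um: tuple = (25.0, 40.0)
    section_tilt_rad: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.spans) - 1.0) > 1e-9:
            raise ValueError("domain spans must sum to 1")
        if self.boundary_width_um < 0:
            raise ValueError("boundary width must be >= 0")

    @property
    def boundary_position_um(self) -> float:
        """True p3/pMN boundary (dorsal limit of the p3 domain)."""
        return (self.spans[0] + self.spans[1]) * self.length_um

    @property
    def logistic_scale_um(self) -> float:
        return self.boundary_width_um / LOGISTIC_BAND_FACTOR


_TYPES = ("floor_plate", "p3", "pMN", "Irx3pos")


def _lognormal(rng, mean, cv, size):
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def generate_embryo_table(config: SyntheticEmbryoConfig, embryo_id: str = "E1"):
    """One synthetic section: (observable table, reference points, truth).

    The observable table has the measured-data schema (embryo_id, x_um,
    y_um, dapi, nkx22, olig2, pax6) in raw section coordinates (offset and
    tilted, so alignment is exercised); truth carries the generator's cell
    types and artefact flags, indexed like the table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    x = rng.uniform(0, cfg.width_um, n)
    y = rng.uniform(0, cfg.length_um, n)

    edges = np.cumsum((0.0,) + cfg.spans) * cfg.length_um
    true_type = np.full(n, "other", dtype=object)
    for k, t in enumerate(_TYPES):
        true_type[(y >= edges[k]) & (y < edges[k + 1])] = t
    true_type[y >= edges[-1]] = _TYPES[-1]
    # logistic mixing at the p3/pMN boundary
    yb, w = cfg.boundary_position_um, cfg.logistic_scale_um
    zone = (true_type == "p3") | (true_type == "pMN")
    if w > 0:
        p_p3 = 1.0 / (1.0 + np.exp((y - yb) / w))
        flip = rng.uniform(size=n) < p_p3
        true_type[zone] = np.where(flip[zone], "p3", "pMN")

    gain = float(np.exp(rng.normal(0.0, cfg.embryo_gain_sd)))
    data = {"embryo_id": embryo_id}
    intens = {}
    for ch in ("nkx22", "olig2", "pax6"):
        v = np.empty(n)
        for t in _TYPES:
            m = cfg.intensity_means[t][ch]
            sel = true_type == t
            v[sel] = _lognormal(rng, m, cfg.intensity_cv, int(sel.sum()))
        intens[ch] = v * gain
    dapi = rng.normal(cfg.dapi_mean, cfg.dapi_sd, n)

    artefact = rng.uniform(size=n) < cfg.artefact_fraction
    dapi[artefact] = cfg.dapi_mean - cfg.artefact_dapi_shift * cfg.dapi_sd + rng.normal(
        0.0, 0.2 * cfg.dapi_sd, int(artefact.sum())
    )
    for ch in intens:
        intens[ch][artefact] *= 0.3

    # raw section frame: translated and tilted
    ox, oy = cfg.section_offset_um
    th = cfg.section_tilt_rad
    c, s = np.cos(th), np.sin(th)
    xr = c * x + s * y + ox
    yr = -s * x + c * y + oy
    table = pd.DataFrame({
        "embryo_id": embryo_id, "x_um": xr, "y_um": yr, "dapi": dapi, **intens,
    })
    refs = pd.DataFrame([{
        "embryo_id": embryo_id,
        "ventral_x": c * (cfg.width_um / 2) + ox,
        "ventral_y": -s * (cfg.width_um / 2) + oy,
        "dorsal_x": c * (cfg.width_um / 2) + s * cfg.length_um + ox,
        "dorsal_y": -s * (cfg.width_um / 2) + c * cfg.length_um + oy,
    }])
    truth = pd.DataFrame({
        "embryo_id": embryo_id,
        "true_type": true_type,
        "artefact": artefact,
        "y_true_um": y,
        "x_true_um": x,
    })
    return table, refs, truth


def generate_cohort(config: SyntheticEmbryoConfig, n_embryos: int, seed: int = 0):
    """Independent sections sharing one config; seeds derived from ``seed``."""
    tables, refs, truths = [], [], []
    for k in range(n_embryos):
        sub = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))
        cfg = replace(config, seed=sub)
        t, r, g = generate_embryo_table(cfg, embryo_id=f"E{k+1}")
        tables.append(t); refs.append(r); truths.append(g)
    return (pd.concat(tables, ignore_index=True),
            pd.concat(refs, ignore_index=True),
            pd.concat(truths, ignore_index=True))


# ---------------------------------------------------------------------------
# benchmark dynamical systems


@dataclass
class BenchmarkSystem:
    name: str
    system: object                    # DynamicalSystem or GRNParameters
    oracle: dict                      # closed-form quantities
    potential: object = None          # callable V(x) for gradient systems


def _double_well():
    rhs = lambda x, s: x - x**3
    jac = lambda x, s: np.array([[1.0 - 3.0 * x[0] ** 2]])
    V = lambda x: x**4 / 4 - x**2 / 2
    sys_ = DynamicalSystem(rhs, jac, n_dim=1, scale=1.0)
    return BenchmarkSystem(
        "double_well_1d", sys_,
        oracle={
            "minima": (-1.0, 1.0), "saddle": 0.0, "delta_V": 0.25,
            "action_unit_diffusion": 0.5,     # 2 * delta_V
            # Kramers mean transition time at temperature eps:
            # tau = 2*pi/sqrt(V''(min)*|V''(saddle)|) * exp(delta_V / eps)
            "kramers_prefactor": 2 * np.pi / np.sqrt(2.0),
        },
        potential=V,
    )


def _gradient_2d(a: float = 1.0):
    V = lambda x: (x[..., 0] ** 2 - 1) ** 2 / 4 + a * x[..., 1] ** 2 / 2
    rhs = lambda x, s: np.array([-(x[0] ** 3 - x[0]), -a * x[1]])
    jac = lambda x, s: np.array([[1.0 - 3 * x[0] ** 2, 0.0], [0.0, -a]])
    sys_ = DynamicalSystem(rhs, jac, n_dim=2, scale=1.0)
    return BenchmarkSystem(
        "gradient_2d", sys_,
        oracle={"minima": ((-1.0, 0.0), (1.0, 0.0)), "saddle": (0.0, 0.0),
                "delta_V": 0.25, "action_unit_diffusion": 0.5},
        potential=V,
    )


def _fold_normal_form():
    rhs = lambda x, s: np.array([s - x[0] ** 2])
    jac = lambda x, s: np.array([[-2.0 * x[0]]])
    sys_ = DynamicalSystem(rhs, jac, n_dim=1, scale=1.0)
    return BenchmarkSystem(
        "fold_normal_form", sys_,
        oracle={"fold_signal": 0.0, "fixed_points": "x = +/- sqrt(s) for s > 0"},
    )


def _toggle_switch():
    """Two-node mutual repression with a graded activating input on node 1."""
    spec = NetworkSpec(
        node_names=("A", "B"),
        sign=np.array([[0, -1], [-1, 0]], dtype=np.int8),
        signal_sign=np.array([1, 0], dtype=np.int8),
    )
    params = GRNParameters(
        spec=spec,
        alpha=np.array([3.0, 3.0]), delta=np.array([1.0, 1.0]),
        K=np.array([[1.0, 0.6], [0.6, 1.0]]), n=np.full((2, 2), 3.0),
        w=np.ones((2, 2)),
        K_s=np.array([0.5, 1.0]), m_s=np.array([2.0, 1.0]),
        w_s=np.array([0.9, 0.0]), w_b=np.array([0.1, 1.0]),
        omega=100.0,
    )
    return BenchmarkSystem("toggle_switch", params,
                           oracle={"bistable": True, "signal_range_hint": (0.2, 2.0)})


_REGISTRY = {
    "double_well_1d": _double_well,
    "gradient_2d": _gradient_2d,
    "fold_normal_form": _fold_normal_form,
    "toggle_switch": _toggle_switch,
}


def generate_benchmark(name: str, **params) -> BenchmarkSystem:
    if name not in _REGISTRY:
        raise KeyError(f"unknown benchmark {name!r}; registry: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**params)


# ---------------------------------------------------------------------------
# reduced-scale model-tissue fixtures


def generate_model_tissue_fixture(genotype: str = "wt", scale: str = "small", seed: int = 0):
    """Fast reduced-scale tissue simulation of the packaged model.

    Returns (TissueSimulation, metadata); metadata records the qualitative
    expectations for the genotype (boundary ordering contrasts).
    """
    from .config import default_model
    from .sde import simulate_tissue

    if genotype not in ("wt", "pax6ko", "o2e33"):
        raise ValueError(f"unknown genotype {genotype!r}")
    sizes = {"small": (30, 20), "medium": (48, 40)}
    if scale not in sizes:
        raise ValueError(f"unknown scale {scale!r}")
    M, cells = sizes[scale]
    params, profile, cfg = default_model(genotype)
    tissue = simulate_tissue(
        params, profile, M=M, cells_per_position=cells,
        duration=float(cfg["simulation"]["duration"]),
        dt=float(cfg["simulation"]["dt"]), seed=seed, genotype=genotype,
        positions=np.linspace(0.02, 0.68, M),
    )
    metadata = {
        "genotype": genotype,
        "seed": seed,
        "expected": {
            "wt": "narrowest boundary",
            "o2e33": "boundary width between wt and pax6ko",
            "pax6ko": "widest boundary, dorsally displaced",
        }[genotype],
    }
    return tissue, metadata
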