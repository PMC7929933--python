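"""Versioned YAML configuration for network specs, parameters and mutants."""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .model import (
    _SIGN_NAMES,
    ConfigurationError,
    GRNParameters,
    MutantPerturbation,
    NetworkSpec,
    SignalProfile,
)

SCHEMA_VERSION = 1


def load_config(source) -> dict:
    """Load a model config from a path, a YAML string, or a dict."""
    if isinstance(source, dict):
        cfg = source
    else:
        text = source
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        cfg = yaml.safe_load(text)
    if cfg.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError("unsupported or missing schema_version")
    return cfg


def default_config() -> dict:
    """Packaged neural-tube parameterisation (Pax6-Olig2-Nkx2.2 core)."""
    text = resources.files("grnprecision").joinpath("data/neural_tube.yaml").read_text()
    return load_config(text)


def build_parameters(cfg: dict) -> GRNParameters:
    net = cfg["network"]
    names = tuple(net["nodes"])
    N = len(names)
    sign = np.zeros((N, N), dtype=np.int8)
    K = np.ones((N, N))
    n = np.ones((N, N))
    w = np.ones((N, N))
    for edge in net.get("interactions", []):
        i = names.index(edge["target"])
        j = names.index(edge["source"])
        sign[i, j] = _SIGN_NAMES[edge["sign"]]
        K[i, j] = float(edge["K"])
        n[i, j] = float(edge["n"])
        w[i, j] = float(edge.get("weight", 1.0))
    signal_sign = np.zeros(N, dtype=np.int8)
    K_s = np.ones(N)
    m_s = np.ones(N)
    w_s = np.zeros(N)
    w_b = np.ones(N)
    for t in net.get("signal_targets", []):
        i = names.index(t["node"])
        signal_sign[i] = _SIGN_NAMES[t["effect"]]
        K_s[i] = float(t["K"])
        m_s[i] = float(t["m"])
        w_s[i] = float(t.get("weight", 1.0))
        w_b[i] = float(t.get("basal", 0.0))
    spec = NetworkSpec(node_names=names, sign=sign, signal_sign=signal_sign)
    p = cfg["params"]
    return GRNParameters(
        spec=spec,
        alpha=np.array([p["alpha"][nm] for nm in names], float),
        delta=np.array([p["delta"][nm] for nm in names], float),
        K=K,
        n=n,
        w=w,
        K_s=K_s,
        m_s=m_s,
        w_s=w_s,
        w_b=w_b,
        omega=float(p.get("omega", 100.0)),
    )


def build_signal_profile(cfg: dict) -> SignalProfile:
    sp = cfg.get("signal_profile", {})
    return SignalProfile(
        s_max=float(sp.get("s_max", 6.0)),
        lam=float(sp.get("lambda_frac", 0.15)),
        noise_sd=float(sp.get("noise_sd", 0.0)),
    )


def build_mutant(cfg: dict, name: str) -> MutantPerturbation:
    if name in ("wt", "WT", None):
        return MutantPerturbation()
    muts = cfg.get("mutants", {})
    if name not in muts:
        raise ConfigurationError(f"unknown mutant {name!r}; known: {sorted(muts)}")
    m = muts[name]
    return MutantPerturbation(
        deleted_nodes=tuple(m.get("deleted_nodes", ())),
        scalings=dict(m.get("scalings", {})),
    )


def default_model(genotype: str = "wt"):
    """(params, signal_profile, cfg) for the packaged defaults, with the
    named genotype perturbation already applied."""
    from .model import apply_mutant

    cfg = default_config()
    params = build_parameters(cfg)
    if genotype not in ("wt", "WT"):
        params = apply_mutant(params, build_mutant(cfg, genotype))
    return params, build_signal_profile(cfg), cfg
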