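"""YAML run configuration.

A run file has up to five sections::

    activation:  {family: logistic, nu_max: 1.0, Lambda: 1.0, V_T: 0.0}
    network:     {tau: 1.0, Gamma: 1.0, Ic: 1.0}
    noise:       {sigma0: 0.1, sigma1: 0.1, sigma2: 0.1, sigma3: 0.0,
                  sigma4: 0.0, C0: 0.4, C1: 0.5, C2: 0.6}
    topology:    {spec: "complete:10"}
    simulation:  {dt: 1.0e-3, t_end: 1.0, n_trials: 1000, seed: 0,
                  store_stride: 0}

Omitted sections and keys fall back to the defaults shown above.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .activation import ActivationSpec
from .graphs import Graph, parse_graph_spec
from .model import NetworkParams
from .simulate import SimulationConfig

__all__ = ["RunConfig", "load_config", "default_config_dict"]


def default_config_dict() -> dict:
    return {
        "activation": {"family": "logistic", "nu_max": 1.0, "Lambda": 1.0, "V_T": 0.0},
        "network": {"tau": 1.0, "Gamma": 1.0, "Ic": 1.0},
        "noise": {
            "sigma0": 0.1,
            "sigma1": 0.1,
            "sigma2": 0.1,
            "sigma3": 0.0,
            "sigma4": 0.0,
            "C0": 0.4,
            "C1": 0.5,
            "C2": 0.6,
        },
        "topology": {"spec": "complete:10"},
        "simulation": {
            "dt": 1e-3,
            "t_end": 1.0,
            "n_trials": 1000,
            "seed": 0,
            "store_stride": 0,
        },
    }


@dataclass(frozen=True)
class RunConfig:
    act: ActivationSpec
    params: NetworkParams
    graph: Graph
    sim: SimulationConfig
    raw: dict


def _merged(defaults: dict, user: dict) -> dict:
    out = {}
    for section, dvals in defaults.items():
        uvals = user.get(section, {}) or {}
        unknown = set(uvals) - set(dvals)
        if unknown:
            raise ValueError(
                f"unknown keys in config section {section!r}: {sorted(unknown)}"
            )
        out[section] = {**dvals, **uvals}
    unknown_sections = set(user) - set(defaults)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    return out

def config_from_dict(user: dict) -> RunConfig:
    cfg = _merged(default_config_dict(), user or {})
    a = cfg["activation"]
    act = ActivationSpec(
        family=a["family"],
        nu_max=float(a["nu_max"]),
        Lambda=float(a["Lambda"]),
        V_T=float(a["V_T"]),
    )
    n, z = cfg["network"], cfg["noise"]
    params = NetworkParams(
        tau=float(n["tau"]),
        Jbar_c=float(n["Gamma"]),
        I_c=float(n["Ic"]),
        sigma=[float(z[f"sigma{k}"]) for k in range(5)],
        C0=float(z["C0"]),
        C1=float(z["C1"]),
        C2=float(z["C2"]),
    )
    graph = parse_graph_spec(cfg["topology"]["spec"])
    s = cfg["simulation"]
    sim = SimulationConfig(
        dt=float(s["dt"]),
        t_end=float(s["t_end"]),
        n_trials=int(s["n_trials"]),
        seed=int(s["seed"]),
        store_stride=int(s["store_stride"]),
    )
    return RunConfig(act, params, graph, sim, cfg)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_dict(user)
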