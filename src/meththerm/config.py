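"""Default parameter values and configuration handling.

The fixed model constants (time constants, projection weights, basal
excitabilities) are the published estimates for the rat circuit; they are
treated as unaffected by the orexin antagonist SB-334867 and held fixed
during inference.  Everything is overridable from a YAML config file whose
sections mirror the module layout (``pk.*``, ``circuit.*``, ``thermo.*``,
``mcmc.*``, ``synth.*``).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Fixed model constants (SB-independent).  Time constants in minutes,
#: projection weights in degrees C, basal excitabilities dimensionless
#: (on the mg/kg concentration scale inside the sigmoids).
DEFAULTS: dict[str, Any] = {
    "pk": {
        "tau_u": 8.25,   # Meth absorption time constant, min
        "tau_d": 57.5,   # Meth elimination time constant, min
        "tau_s": 10.0,   # injection-stress decay time constant, min
    },
    "circuit": {
        "gamma_Exc": -0.357,
        "gamma_Inh": -1.335,
        "gamma_HD": -3.69,
        "gamma_SPN": -3.35,
        "w_Exc_Med": 9.89,
        "w_Inh_Med": 6.38,
        "w_HD_SPN": 5.66,
        "variant": "base",
        "w_Inh_HD": 5.0,
        "inhib_cap": 1.0,
        # recalibrate gamma_SPN so the resting drive is zero (see circuit.py)
        "raw_gamma_spn": False,
        # SB-affected sensitivities; per-SB-dose truth lives in synth.scenario
        "w_S": 1.2,
        "w_Exc": 0.85,
        "w_Inh": 0.66,
        "w_HD": 0.70,
    },
    "thermo": {
        "tau_T": 89.2,   # temperature response time constant, min
        "T0": 37.0,      # baseline body temperature, degC
        "dt": 0.1,       # integrator step, min
    },
    "mcmc": {
        "n_steps": 50_000,
        "burn_in": 10_000,
        "thin": 10,
        "seed": 42,
    },
    "synth": {
        "n_per_group": 7,
        "t_start": -50.0,
        "t_end": 180.0,
        "dt_sample": 2.0,
        "pretreat_time": -30.0,
        "meth_time": 0.0,
        "sb_doses": [0, 10, 30],
        "meth_doses": [0, 1, 5, 10],
        "noise_sd": 0.3,
        "ar1": 0.5,
        "baseline_sd": 0.2,
        # per-SB-dose generating truth (w_S, w_Exc, w_Inh, w_HD); chosen so
        # the qualitative dose orderings of the fitted study hold
        "scenario": {
            0:  {"w_S": 1.2, "w_Exc": 0.85, "w_Inh": 0.66, "w_HD": 0.70},
            10: {"w_S": 0.85, "w_Exc": 0.62, "w_Inh": 0.60, "w_HD": 0.90},
            30: {"w_S": 0.75, "w_Exc": 0.40, "w_Inh": 0.35, "w_HD": 1.15},
        },
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict[str, Any]:
    """Return the full config dict: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path!r} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Short stable hash of a config, for run logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
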