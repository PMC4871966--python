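"""Config-file handling for the command-line interface.

Schema (YAML or JSON — JSON is a YAML subset):

    params:   {sigma_inf: 5, sigma_tilde: 1, s: 1, tau: 1}
    schedule: {kind: sinusoidal, omega: 6.2832, mean: 1.0, amplitude: 1.0,
               phase: 0.0}           # or kind: constant {lam0}, or
                                     # kind: piecewise {times, values, interp}
    history:  {x0: 2.0}              # constant cubed-radius history
    solver:   {dt: 0.01, t_end: 200.0}   # optional
"""

from __future__ import annotations

import json

import yaml

from .model import ModelParams
from .solver import HistoryFunction
from .therapy import schedule_from_dict

__all__ = ["load_config", "dump_config"]


def load_config(path):
    """Read a config file into (params, schedule, history, solver_opts)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "params" not in raw or "schedule" not in raw:
        raise ValueError("config must be a mapping with 'params' and 'schedule'")
    params = ModelParams.from_dict(raw["params"])
    schedule = schedule_from_dict(raw["schedule"])
    history = None
    if "history" in raw:
        h = raw["history"]
        if "x0" not in h:
            raise ValueError("history must give a constant 'x0'")
        history = HistoryFunction.constant(float(h["x0"]))
    solver_opts = dict(raw.get("solver", {}))
    return params, schedule, history, solver_opts


def dump_config(path, params, schedule, x0=None, solver_opts=None):
    """Write a config file (JSON for .json paths, YAML otherwise)."""
    doc = {"params": params.to_dict(), "schedule": schedule.to_dict()}
    if x0 is not None:
        doc["history"] = {"x0": float(x0)}
    if solver_opts:
        doc["solver"] = dict(solver_opts)
    text = (json.dumps(doc, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(doc, sort_keys=False))
    with open(path, "w") as fh:
        fh.write(text)
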