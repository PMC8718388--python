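"""Configuration loading: YAML/JSON records mirroring the CLI flags.

Schema::

    model:
      alpha: 7.1
      beta: 0.8
      m: 1.456
    allee:
      name: monod
      delta: 0.03
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import yaml

from .allee import AlleeFunction, make_allee
from .model import ModelParams

__all__ = ["load_config", "dump_config"]


def load_config(path) -> Tuple[ModelParams, AlleeFunction]:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    model = data["model"]
    allee = data["allee"]
    return (ModelParams(float(model["alpha"]), float(model["beta"]),
                        float(model["m"])),
            make_allee(allee["name"], float(allee["delta"])))


def dump_config(p: ModelParams, h: AlleeFunction, path) -> None:
    data = {"model": {"alpha": p.alpha, "beta": p.beta, "m": p.m},
            "allee": {"name": h.name, "delta": h.delta}}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
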