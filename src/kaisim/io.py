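"""Trajectory/sweep serialization and run manifests.

Time series go to CSV (column order fixed: t, Dbar, Xbar, P_CA, P_CBA,
releases, then one D_k column per recorded hexamer); run manifests to
JSON with the fully resolved parameter set, controls and seed, so every
output file is regenerable bit-exactly from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .params import ModelParams, Trajectory
from .simulate import SimControl

__all__ = ["write_trajectory", "read_trajectory", "write_manifest", "load_manifest"]


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: str | Path, params: ModelParams, control: SimControl,
                   extra: dict | None = None) -> Path:
    path = Path(path)
    manifest = {
        "kaisim_version": __version__,
        "params": params.to_dict(),
        "control": dataclasses.asdict(control),
        "seed": control.seed,
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    return path


def load_manifest(path: str | Path) -> tuple[ModelParams, SimControl, dict]:
    manifest = json.loads(Path(path).read_text())
    params = ModelParams.from_dict(manifest["params"])
    ctl = dict(manifest["control"])
    ctl["record_hexamers"] = tuple(ctl.get("record_hexamers", ()))
    control = SimControl(**ctl)
    return params, control, manifest
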