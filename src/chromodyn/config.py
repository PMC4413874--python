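"""Plain-config (YAML/JSON) serialisation and named presets.

Presets encode the two condensin regimes: interphase (G1) with
dissociation probability 1e-3 per unit time, and mitosis with a switch to
1e-4 at t=0 after an interphase equilibration stretch.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .integrate import Phase, SimulationConfig
from .params import SimulationParams

__all__ = ["config_to_dict", "config_from_dict", "save_config", "load_config", "preset"]

PathLike = Union[str, Path]


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_beads": config.n_beads,
        "spacing": config.spacing,
        "bp_per_bead": config.bp_per_bead,
        "site_interval_bp": config.site_interval_bp,
        "condensin_sites": (
            None
            if config.condensin_sites is None
            else [int(s) for s in config.condensin_sites]
        ),
        "params": config.params.to_dict(),
        "phases": [{"steps": ph.steps, "p": ph.p} for ph in config.phases],
        "stride": config.stride,
        "seed": config.seed,
        "markers": list(config.markers) if config.markers is not None else None,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    params = d.get("params", {})
    if isinstance(params, dict):
        params = SimulationParams.from_dict(params)
    phases = [Phase(steps=ph["steps"], p=ph.get("p")) for ph in d.get("phases", [])]
    markers = d.get("markers")
    return SimulationConfig(
        n_beads=d.get("n_beads", 2000),
        spacing=d.get("spacing", 15.0),
        bp_per_bead=d.get("bp_per_bead", 150.0),
        site_interval_bp=d.get("site_interval_bp"),
        condensin_sites=d.get("condensin_sites"),
        params=params,
        phases=phases or [Phase(steps=100_000)],
        stride=d.get("stride", 1000),
        seed=d.get("seed", 0),
        markers=tuple(markers) if markers else None,
    )


def save_config(config: SimulationConfig, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: PathLike) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def preset(
    name: str,
    n_beads: int = 2000,
    steps: int = 1_000_000,
    interphase_steps: int = 500_000,
    stride: int = 5000,
    seed: int = 0,
) -> SimulationConfig:
    """Named run configurations.

    ``interphase-type1|2``: constant p=1e-3.  ``mitosis-type1|2``:
    interphase equilibration then the p switch to 1e-4 at t=0 for
    ``steps`` further steps.
    """
    name = name.lower()
    if name not in {
        "interphase-type1",
        "interphase-type2",
        "mitosis-type1",
        "mitosis-type2",
    }:
        raise ValueError(f"unknown preset {name!r}")
    regime, mode = name.split("-")
    params = SimulationParams(p=1e-3, mode=mode)
    if regime == "interphase":
        phases = [Phase(steps=steps)]
    else:
        phases = [Phase(steps=interphase_steps), Phase(steps=steps, p=1e-4)]
    return SimulationConfig(
        n_beads=n_beads,
        site_interval_bp=10_000.0,
        params=params,
        phases=phases,
        stride=stride,
        seed=seed,
    )
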