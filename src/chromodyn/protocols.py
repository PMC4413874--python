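"""Canonical measurement protocols for the model's benchmark observables.

These wrap the simulator and observables into the standard recipes used to
characterise the model: equilibrate a chain at desk scale, then measure
the 30 ms displacement distribution, the mean linker tension, and the
alpha-angle mode.  The same protocols back the test suite, the examples
and the reproduction script, so the numbers quoted in the documentation
are always produced by this code path.

Problem sizes: local observables (displacement, tension, angles) are
self-averaging over beads and frames, so a 300-bead chain equilibrated for
3e5 steps with a 1.1e6-step production stretch gives percent-level
precision; chain-scale observables in the scaled condensation protocol
use a 200-bead chain with proportionally denser condensin sites (see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .calibrate import equilibrated_chain_positions
from .chain import build_chain
from .integrate import Phase, SimulationConfig, run
from .observables import (
    alpha_angle_mode,
    alpha_angles,
    displacement_distribution,
    mean_linker_tension,
)
from .params import SimulationParams
from .trajectory import Trajectory

__all__ = [
    "local_equilibrium_run",
    "EQUILIBRATION_STEPS",
    "displacement_stats_30ms",
    "tension_estimate",
    "alpha_mode_estimate",
    "scaled_condensation_run",
]

#: Steps discarded as equilibration in the local-observable protocol.
EQUILIBRATION_STEPS = 300_000


def local_equilibrium_run(
    params: Optional[SimulationParams] = None,
    n_beads: int = 300,
    total_steps: int = 1_400_000,
    stride: int = 2500,
    seed: int = 3,
) -> Trajectory:
    """Equilibrated chain without condensin for local-dynamics measurements.

    Starts from a random-direction chain geometry (local angles begin near
    their equilibrium distribution, which shortens equilibration) and runs
    ``total_steps`` midpoint steps.  Analyses should discard the first
    ``EQUILIBRATION_STEPS`` steps.
    """
    if params is None:
        params = SimulationParams()
    state = build_chain(
        n_beads,
        positions=equilibrated_chain_positions(n_beads, spacing=params.c2, seed=seed),
        site_interval_bp=None,
    )
    cfg = SimulationConfig(
        n_beads=n_beads,
        site_interval_bp=None,
        params=params,
        phases=[Phase(steps=total_steps)],
        stride=stride,
        seed=seed,
    )
    return run(cfg, state=state)


def _discard_frames(traj: Trajectory) -> int:
    stride = int(traj.step_index[1] - traj.step_index[0]) if traj.n_frames > 1 else 1
    return EQUILIBRATION_STEPS // max(stride, 1)


def displacement_stats_30ms(traj: Trajectory) -> Tuple[float, float]:
    """Mean and SD (nm) of 3D bead displacements over 30 ms windows,
    pooled over beads and overlapping window starts.

    The window is the closest integer number of frames to 30 ms (within
    0.1% at the default stride)."""
    fs = traj.frame_seconds
    lag = max(1, int(round(0.03 / fs)))
    stats = displacement_distribution(
        traj, window=lag * fs, discard_frames=_discard_frames(traj)
    )
    return stats.mean, stats.sd


def tension_estimate(traj: Trajectory) -> float:
    """Mean |Ks (d - c2)| (pN) over equilibrated frames and linkers."""
    return mean_linker_tension(traj, discard_frames=_discard_frames(traj))


def alpha_mode_estimate(traj: Trajectory) -> float:
    """Histogram mode (5-degree bins, quadratically refined) of the pooled
    alpha-angle sample over equilibrated frames."""
    discard = _discard_frames(traj)
    angs = np.concatenate(
        [alpha_angles(traj.state(k)) for k in range(discard, traj.n_frames)]
    )
    return alpha_angle_mode(angs)


@dataclass
class ScaledCondensationRun:
    """One run of the scaled condensation protocol."""

    trajectory: Trajectory
    mode: Optional[str]  # None = no condensin control
    seed: int


def scaled_condensation_run(
    mode: Optional[str],
    seed: int,
    n_beads: int = 200,
    site_interval_bp: float = 2250.0,
    interphase_steps: int = 400_000,
    mitotic_steps: int = 800_000,
    p_interphase: float = 1e-3,
    p_mitotic: Optional[float] = 1e-4,
    stride: int = 4000,
) -> ScaledCondensationRun:
    """Desk-scale condensation experiment.

    The chain length and condensin-site interval are scaled down together
    (the full-scale chain, 2000 beads with 10 kb sites, needs ~1e9 steps
    to traverse its loop-formation timescale).  ``mode=None`` runs the
    matched no-condensin control.  The schedule is ``interphase_steps`` at
    ``p_interphase`` followed by ``mitotic_steps`` after the dissociation
    probability switches to ``p_mitotic`` at t=0.
    """
    state = build_chain(
        n_beads,
        positions=equilibrated_chain_positions(n_beads, seed=seed),
        site_interval_bp=site_interval_bp if mode else None,
    )
    params = SimulationParams(mode=mode or "type1", p=p_interphase)
    phases = [Phase(steps=interphase_steps)]
    if p_mitotic is not None:
        phases.append(Phase(steps=mitotic_steps, p=p_mitotic))
    else:
        phases.append(Phase(steps=mitotic_steps))
    markers = (n_beads // 10, n_beads - n_beads // 10)
    cfg = SimulationConfig(
        n_beads=n_beads,
        site_interval_bp=None,
        params=params,
        phases=phases,
        stride=stride,
        seed=seed,
        markers=markers,
    )
    return ScaledCondensationRun(trajectory=run(cfg, state=state), mode=mode, seed=seed)
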