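"""Midpoint Brownian-dynamics stepping and run orchestration.

The midpoint scheme evaluates the deterministic forces twice per step: the
half-step position is advanced with the full force at the step start, the
full step then combines the *step-start entropic draw* with the
deterministic forces re-evaluated at the half-step position:

    x_half = x0 + (dt/2) * [F_ent(x0) + F_det(x0)]
    x1     = x0 + dt     * [F_ent(x0) + F_det(x_half)]

The condensin bond set is updated once per step, before the force
evaluations.  :func:`midpoint_step` is the readable reference used in
tests; :func:`run` drives the compiled kernel over a phase schedule
(e.g. the interphase -> mitosis dissociation-probability switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .bonds import BondSet, update_bonds
from .chain import ChainState, build_chain
from .forces import (
    attraction_force,
    condensin_force,
    entropic_force,
    repulsion_force,
    tension_force,
)
from .params import SimulationParams, TimeMapping
from .trajectory import Trajectory

__all__ = [
    "midpoint_step",
    "run",
    "Phase",
    "SimulationConfig",
    "ConfigError",
    "IntegrationError",
]

_EMPTY_NOISE = np.zeros((0, 0, 3))


class IntegrationError(RuntimeError):
    """Raised when integration produces non-finite positions."""

    def __init__(self, message: str, state: Optional[ChainState] = None):
        super().__init__(message)
        self.state = state


def midpoint_step(
    state: ChainState,
    bonds: BondSet,
    params: SimulationParams,
    rng: np.random.Generator,
    entropic: Optional[np.ndarray] = None,
    update_bond_set: bool = True,
) -> Tuple[ChainState, BondSet]:
    """One reference midpoint step.  Returns the new state and bond set.

    ``entropic`` injects the per-bead entropic force (pN) for the step;
    otherwise it is drawn from ``rng``.
    """
    if params.dt is not None:
        dt = params.dt
    else:
        dt = params.stable_dt(state.condensin_sites.size > 1)
    if update_bond_set and state.condensin_sites.size > 1:
        bonds = update_bonds(state, bonds, params, rng)
    if entropic is None:
        entropic = entropic_force(state, params, rng)

    def det(s: ChainState) -> np.ndarray:
        return (
            tension_force(s, params, rng)
            + repulsion_force(s, params, rng)
            + attraction_force(s, params, rng)
            + condensin_force(s, bonds, params, rng)
        )

    x0 = state.positions
    half = state.copy()
    half.positions = x0 + 0.5 * dt * (entropic + det(state))
    x1 = x0 + dt * (entropic + det(half))
    if not np.isfinite(x1).all():
        raise IntegrationError("non-finite positions after step", state)
    out = state.copy()
    out.positions = x1
    return out, bonds


@dataclass(frozen=True)
class Phase:
    """A stretch of the schedule: ``steps`` integration steps at
    dissociation probability ``p`` (None keeps the previous value)."""

    steps: int
    p: Optional[float] = None


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run.

    Geometry (bead count, spacing, genomic calibration, condensin site
    placement), force-field parameters, the phase schedule, the recording
    stride and the seed.
    """

    n_beads: int = 2000
    spacing: float = 15.0
    bp_per_bead: float = 150.0
    site_interval_bp: Optional[float] = 10_000.0
    condensin_sites: Optional[Sequence[int]] = None
    params: SimulationParams = field(default_factory=SimulationParams)
    phases: List[Phase] = field(default_factory=lambda: [Phase(steps=100_000)])
    stride: int = 1000
    seed: int = 0
    markers: Optional[Tuple[int, int]] = None

    def validate(self) -> None:
        """Collect every configuration problem into a single error."""
        errors = []
        if self.n_beads < 3:
            errors.append(f"n_beads must be >= 3, got {self.n_beads}")
        if self.spacing <= 0:
            errors.append(f"spacing must be positive, got {self.spacing}")
        if self.bp_per_bead <= 0:
            errors.append(f"bp_per_bead must be positive, got {self.bp_per_bead}")
        if self.stride < 1:
            errors.append(f"stride must be >= 1, got {self.stride}")
        if not self.phases:
            errors.append("at least one phase is required")
        for k, ph in enumerate(self.phases):
            if ph.steps < 0:
                errors.append(f"phase {k}: steps must be >= 0, got {ph.steps}")
            if ph.p is not None and not 0 <= ph.p <= 1:
                errors.append(f"phase {k}: p must lie in [0, 1], got {ph.p}")
        if self.site_interval_bp is not None and self.condensin_sites is not None:
            errors.append("give either site_interval_bp or condensin_sites, not both")
        if self.markers is not None:
            a, b = self.markers
            if not (0 <= a < self.n_beads and 0 <= b < self.n_beads):
                errors.append(f"markers {self.markers} out of bead range")
        if errors:
            raise ConfigError("\n".join(errors))

    def build_state(self) -> ChainState:
        return build_chain(
            self.n_beads,
            spacing=self.spacing,
            bp_per_bead=self.bp_per_bead,
            condensin_sites=self.condensin_sites,
            site_interval_bp=self.site_interval_bp,
        )


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def _phase_seed(seed: int, phase_index: int) -> int:
    """Derived per-phase kernel seed, kept within int32 range."""
    return int((seed * 1_000_003 + 7919 * (phase_index + 1)) % 2_147_483_647)


def run(
    config: SimulationConfig,
    state: Optional[ChainState] = None,
    bonds: Optional[BondSet] = None,
    cylinder_radius: float = -1.0,
) -> Trajectory:
    """Execute the phase schedule and return the recorded trajectory.

    ``state`` supplies a prepared starting conformation (e.g. from the
    initializer pipeline); otherwise a straight chain is built from the
    config geometry.  Frame 0 is the initial state; frames are recorded
    every ``config.stride`` steps.
    """
    config.validate()
    if state is None:
        state = config.build_state()
    else:
        state = state.copy()
    params = config.params
    sites_present = state.condensin_sites.size > 1
    dt = params.dt if params.dt is not None else params.stable_dt(sites_present)
    pos = np.ascontiguousarray(state.positions, dtype=float)
    chain_id = np.ascontiguousarray(state.chain_id, dtype=np.int64)
    sites = np.ascontiguousarray(state.condensin_sites, dtype=np.int64)

    # site-local bond arrays for the kernel
    site_lookup = {int(s): k for k, s in enumerate(sites)}
    S = len(sites)
    cap = max(4, S * params.degree_cap)
    bond_i = np.zeros(cap, np.int64)
    bond_j = np.zeros(cap, np.int64)
    cd_i = np.zeros(cap, np.int64)
    cd_j = np.zeros(cap, np.int64)
    cd_t = np.zeros(cap, np.int64)
    nb = 0
    if bonds is not None:
        for a, b in bonds.pairs():
            bond_i[nb] = site_lookup[a]
            bond_j[nb] = site_lookup[b]
            nb += 1
    ncd = 0

    all_frames, all_steps, all_bonds, all_counts = [], [], [], []
    p_current = params.p
    step_offset = 0
    for k, phase in enumerate(config.phases):
        if phase.p is not None:
            p_current = phase.p
        rec, bond_rec, bond_counts, _, nb, ncd = _kernels.simulate_phase(
            pos, chain_id, phase.steps, dt,
            params.c1, params.Ks, params.c2, params.c3, params.c4,
            params.Kcondensin, params.c5, params.attraction_radius,
            params.repulsion_radius, params.bead_diameter,
            p_current, sites, params.degree_cap, params.rebond_window,
            bond_i, bond_j, nb, cd_i, cd_j, cd_t, ncd,
            _phase_seed(config.seed, k), config.stride, cylinder_radius, 4.0,
            _EMPTY_NOISE,
        )
        if not np.isfinite(pos).all():
            raise IntegrationError(
                f"non-finite positions in phase {k}",
                ChainState(rec[-2].astype(float), sites, chain_id, config.bp_per_bead)
                if rec.shape[0] >= 2 else None,
            )
        start = 0 if k == 0 else 1  # drop duplicated boundary frame
        steps_here = np.arange(rec.shape[0]) * config.stride + step_offset
        all_frames.append(rec[start:])
        all_steps.append(steps_here[start:])
        all_bonds.append(bond_rec[start:])
        all_counts.append(bond_counts[start:])
        step_offset += phase.steps

    # bond records are site-local indices; convert to bead indices
    bonds_arr = np.concatenate(all_bonds)
    mask = bonds_arr >= 0
    converted = bonds_arr.copy()
    if S:
        converted[mask] = sites[bonds_arr[mask]]
    schedule = []
    p_log = params.p
    for ph in config.phases:
        if ph.p is not None:
            p_log = ph.p
        schedule.append((ph.steps, p_log))
    mapping = TimeMapping(dt=dt)
    return Trajectory(
        frames=np.concatenate(all_frames),
        step_index=np.concatenate(all_steps),
        seconds_per_step=mapping.seconds_per_step,
        sites=sites,
        chain_id=chain_id,
        bp_per_bead=config.bp_per_bead,
        bonds=converted,
        bond_counts=np.concatenate(all_counts),
        params=params.to_dict(),
        seed=config.seed,
        schedule=schedule,
        markers=config.markers,
    )
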