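"""Time-ordered simulation output: frames, bonds, provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .bonds import BondSet
from .chain import ChainState

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Recorded frames of one simulation run.

    ``frames`` are float32 positions ``(n_frames, n_beads, 3)`` in nm;
    ``step_index`` gives the integration step of each frame and
    ``seconds_per_step`` the in-vivo time mapping.  ``bonds`` holds the
    condensin pairs active at each frame as bead-index pairs padded with -1.
    The exact configuration that produced the run travels with the data
    (``params``, ``seed``, ``schedule``).
    """

    frames: np.ndarray
    step_index: np.ndarray
    seconds_per_step: float
    sites: np.ndarray
    chain_id: np.ndarray
    bp_per_bead: float
    bonds: Optional[np.ndarray] = None
    bond_counts: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)
    seed: int = 0
    schedule: List[Tuple[int, float]] = field(default_factory=list)
    markers: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, n, 3), got {self.frames.shape}")
        self.step_index = np.asarray(self.step_index, dtype=np.int64)
        if self.step_index.shape[0] != self.frames.shape[0]:
            raise ValueError("step_index length must match frame count")
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """In-vivo time of each frame (s)."""
        return self.step_index * self.seconds_per_step

    @property
    def frame_seconds(self) -> float:
        """Seconds between consecutive frames (uniform stride assumed)."""
        if self.n_frames < 2:
            return 0.0
        strides = np.diff(self.step_index)
        return float(strides[0]) * self.seconds_per_step

    def state(self, frame: int) -> ChainState:
        """The chain state at one frame (positions promoted to float64)."""
        return ChainState(
            positions=self.frames[frame].astype(float),
            condensin_sites=self.sites,
            chain_id=self.chain_id,
            bp_per_bead=self.bp_per_bead,
        )

    def bond_set(self, frame: int) -> BondSet:
        """Active condensin bonds at one frame as bead-index pairs."""
        if self.bonds is None:
            return BondSet()
        rows = self.bonds[frame]
        pairs = set()
        for a, b in rows:
            if a < 0:
                break
            pairs.add((int(min(a, b)), int(max(a, b))))
        return BondSet(bonds=pairs)

    def states(self):
        for k in range(self.n_frames):
            yield self.state(k)

    def slice(self, start: int, stop: Optional[int] = None) -> "Trajectory":
        """Sub-trajectory over a frame range (views, not copies)."""
        sl = np.s_[start:stop]
        return Trajectory(
            frames=self.frames[sl],
            step_index=self.step_index[sl],
            seconds_per_step=self.seconds_per_step,
            sites=self.sites,
            chain_id=self.chain_id,
            bp_per_bead=self.bp_per_bead,
            bonds=None if self.bonds is None else self.bonds[sl],
            bond_counts=None if self.bond_counts is None else self.bond_counts[sl],
            params=self.params,
            seed=self.seed,
            schedule=self.schedule,
            markers=self.markers,
        )
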