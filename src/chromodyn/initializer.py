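"""Starting-conformation pipeline: Hilbert-curve seeding, expansion to an
open cylinder, and relaxation to a compaction steady state.

The production pipeline mirrors how a crowded interphase nucleus is
emulated: the chain is first laid along a space-filling 3D Hilbert curve
inside a compact cube (self-avoiding by construction), then allowed to
expand under the force field inside a cylindrical wall of 200 nm diameter,
and finally relaxed without constraints until the marker-pair distance
reaches a plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .bonds import BondSet
from .chain import ChainState
from .integrate import Phase, SimulationConfig, run
from .params import SimulationParams

__all__ = [
    "hilbert_curve_points",
    "hilbert_seed",
    "expand_to_cylinder",
    "relax_chain",
    "RelaxationTimeout",
]


def _transpose_to_axes(X: np.ndarray, bits: int) -> np.ndarray:
    """Skilling's transform: Hilbert transpose form -> grid coordinates."""
    n = X.shape[0]
    N = 2 << (bits - 1)
    # Gray decode
    t = X[n - 1] >> 1
    for i in range(n - 1, 0, -1):
        X[i] ^= X[i - 1]
    X[0] ^= t
    # undo excess work
    Q = 2
    while Q != N:
        P = Q - 1
        for i in range(n - 1, -1, -1):
            if X[i] & Q:
                X[0] ^= P
            else:
                t = (X[0] ^ X[i]) & P
                X[0] ^= t
                X[i] ^= t
        Q <<= 1
    return X


def _index_to_transpose(d: int, bits: int, n: int = 3) -> np.ndarray:
    """Distribute the 3*bits bits of ``d`` over the transpose form
    (most-significant triple first; axis 0 gets the leading bit)."""
    X = np.zeros(n, dtype=np.int64)
    for k in range(bits):  # k = 0 is the most significant triple
        for axis in range(n):
            bit = (d >> (n * (bits - 1 - k) + (n - 1 - axis))) & 1
            X[axis] |= bit << (bits - 1 - k)
    return X


def hilbert_curve_points(order: int) -> np.ndarray:
    """Integer grid vertices of the 3D Hilbert curve of a given order.

    Returns an ``(8**order, 3)`` array; consecutive vertices differ by one
    unit step and every cell of the ``2**order`` cube is visited once.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    m = 8**order
    pts = np.empty((m, 3), dtype=np.int64)
    for d in range(m):
        pts[d] = _transpose_to_axes(_index_to_transpose(d, order), order)
    return pts


def hilbert_seed(n_beads: int, cube_edge: float = 150.0) -> np.ndarray:
    """Self-avoiding starting positions along a Hilbert curve in a cube.

    The smallest curve order with at least ``n_beads`` vertices is used and
    the first ``n_beads`` vertices are rescaled to fill ``[0, cube_edge]^3``
    (nm).  Consecutive beads are exactly one curve step apart.
    """
    if n_beads < 2:
        raise ValueError(f"n_beads must be >= 2, got {n_beads}")
    if cube_edge <= 0:
        raise ValueError(f"cube_edge must be positive, got {cube_edge}")
    order = 1
    while 8**order < n_beads:
        order += 1
    pts = hilbert_curve_points(order)[:n_beads]
    cells = 2**order
    step = cube_edge / cells
    return (pts + 0.5) * step


@dataclass
class RelaxationResult:
    state: ChainState
    steps_used: int
    plateau_mean: float


class RelaxationTimeout(RuntimeError):
    """No compaction plateau within the step budget; carries the last state."""

    def __init__(self, message: str, state: ChainState, steps_used: int):
        super().__init__(message)
        self.state = state
        self.steps_used = steps_used


def _principal_frame(positions: np.ndarray) -> np.ndarray:
    """Rotation matrix whose last row is the principal axis (maps it to z)."""
    centered = positions - positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    R = vt[::-1].copy()  # principal axis last -> z
    if np.linalg.det(R) < 0:
        R[0] *= -1
    return R


def expand_to_cylinder(
    state: ChainState,
    diameter: float,
    params: SimulationParams,
    steps: int,
    seed: int = 0,
    stride: Optional[int] = None,
) -> ChainState:
    """Brownian dynamics inside a hard cylindrical wall of given diameter.

    The wall is enforced by radial clamping about the chain's principal
    axis (rotated to z); beads that step outside are projected back to the
    wall.  With ``steps=0`` the input is returned unchanged.
    """
    if diameter <= params.bead_diameter:
        raise ValueError(
            f"cylinder diameter {diameter} nm must exceed the bead diameter"
        )
    if steps == 0:
        return state.copy()
    out = state.copy()
    R = _principal_frame(out.positions)
    centre = out.positions.mean(axis=0)
    out.positions = (out.positions - centre) @ R.T
    config = SimulationConfig(
        n_beads=state.n_beads,
        bp_per_bead=state.bp_per_bead,
        site_interval_bp=None,
        params=params,
        phases=[Phase(steps=steps)],
        stride=stride or max(1, steps // 10),
        seed=seed,
    )
    traj = run(config, state=out, cylinder_radius=diameter / 2.0)
    out.positions = traj.frames[-1].astype(float)
    return out


def relax_chain(
    state: ChainState,
    params: SimulationParams,
    plateau_window: int = 100_000,
    plateau_tol: float = 0.02,
    max_steps: int = 4_000_000,
    markers: Optional[Tuple[int, int]] = None,
    seed: int = 0,
    bonds: Optional[BondSet] = None,
) -> RelaxationResult:
    """Run until the marker-distance moving average plateaus.

    The marker distance is averaged over windows of ``plateau_window``
    steps; the chain is considered relaxed when consecutive window means
    differ by less than ``plateau_tol`` (relative).  Raises
    :class:`RelaxationTimeout` carrying the last state if no plateau is
    found within ``max_steps``.
    """
    if markers is None:
        markers = state.default_markers()
    a, b = markers
    current = state.copy()
    prev_mean = None
    steps_used = 0
    stride = max(1, plateau_window // 20)
    window_index = 0
    while steps_used < max_steps:
        config = SimulationConfig(
            n_beads=current.n_beads,
            bp_per_bead=current.bp_per_bead,
            site_interval_bp=None,
            params=params,
            phases=[Phase(steps=plateau_window)],
            stride=stride,
            seed=seed + window_index,
        )
        config.condensin_sites = None
        traj = run(config, state=current, bonds=bonds)
        bonds = traj.bond_set(traj.n_frames - 1)
        current.positions = traj.frames[-1].astype(float)
        d = np.linalg.norm(
            traj.frames[:, a].astype(float) - traj.frames[:, b].astype(float), axis=1
        )
        mean = float(d.mean())
        steps_used += plateau_window
        window_index += 1
        if prev_mean is not None and abs(mean - prev_mean) < plateau_tol * prev_mean:
            return RelaxationResult(current, steps_used, mean)
        prev_mean = mean
    raise RelaxationTimeout(
        f"no compaction plateau within {max_steps} steps", current, steps_used
    )
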