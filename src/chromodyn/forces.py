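"""Reference (numpy) implementation of the five force terms.

These functions are the readable contract for the force field and the
oracle against which the compiled production kernel is tested.  All forces
are pN vectors per bead; pairwise terms obey Newton's third law.

Force summary (bead *i*):

* entropic: magnitude ``c1`` in an independent uniform random direction,
  redrawn every step;
* tension: ``Ks*(d_{i,i+1}-c2)*u_{i,i+1} + Ks*(d_{i,i-1}-c2)*u_{i,i-1}``;
* repulsion: magnitude ``c3`` for pair distances below the 10 nm bead
  diameter, ``c3/(d/10nm)^12`` between 10 and 15 nm, zero beyond;
* attraction: ``c4 * d_{i,i+/-2}`` towards the second neighbours;
* condensin: ``Kcondensin*(d-c5)*u`` per active bond, zero beyond the
  40 nm interaction radius.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .bonds import BondSet
from .chain import ChainState
from .params import SimulationParams

__all__ = [
    "entropic_force",
    "tension_force",
    "repulsion_force",
    "attraction_force",
    "condensin_force",
    "total_force",
    "random_unit_vectors",
    "repulsion_magnitude",
]


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent directions uniform on the unit sphere."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero draw has probability zero; substitute an arbitrary direction
    norms[norms < 1e-300] = 1.0
    return v / norms


def entropic_force(
    state: ChainState, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Random kick of magnitude ``c1`` per bead (redrawn each call)."""
    return params.c1 * random_unit_vectors(state.n_beads, rng)


def _unit_vectors(vec: np.ndarray, rng: Optional[np.random.Generator]) -> np.ndarray:
    """Row-normalise; coincident points get a random direction (logged event)."""
    d = np.linalg.norm(vec, axis=1, keepdims=True)
    degenerate = d[:, 0] < 1e-12
    if degenerate.any():
        sub = rng if rng is not None else np.random.default_rng(0)
        vec = vec.copy()
        vec[degenerate] = random_unit_vectors(int(degenerate.sum()), sub)
        d = np.where(degenerate[:, None], 1.0, d)
    return vec / d


def tension_force(
    state: ChainState,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Hookean linker tension toward both chain neighbours (end beads: one)."""
    pos = state.positions
    F = np.zeros_like(pos)
    vec = pos[1:] - pos[:-1]
    d = np.linalg.norm(vec, axis=1)
    u = _unit_vectors(vec, rng)
    fmag = params.Ks * (d - params.c2)
    pair = fmag[:, None] * u
    same = state.chain_id[:-1] == state.chain_id[1:]
    pair[~same] = 0.0
    F[:-1] += pair
    F[1:] -= pair
    return F


def repulsion_magnitude(d: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Scalar repulsion profile: c3 below 10 nm, soft-core 12th-power decay
    to 15 nm, zero beyond.  Continuous at the 10 nm bead diameter."""
    d = np.asarray(d, dtype=float)
    scaled = d / params.bead_diameter
    with np.errstate(divide="ignore"):
        soft = params.c3 / scaled**12
    mag = np.where(d < params.bead_diameter, params.c3, soft)
    return np.where(d > params.repulsion_radius, 0.0, mag)


def repulsion_force(
    state: ChainState,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Excluded-volume repulsion between all bead pairs within 15 nm (O(n^2))."""
    pos = state.positions
    n = state.n_beads
    F = np.zeros_like(pos)
    diff = pos[None, :, :] - pos[:, None, :]
    d = np.linalg.norm(diff, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    dd = d[iu, ju]
    close = dd <= params.repulsion_radius
    iu, ju, dd = iu[close], ju[close], dd[close]
    mag = repulsion_magnitude(dd, params)
    u = _unit_vectors(diff[iu, ju], rng)
    pair = mag[:, None] * u  # direction i -> j; force on i is away from j
    np.add.at(F, iu, -pair)
    np.add.at(F, ju, pair)
    return F


def attraction_force(
    state: ChainState,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Weak pull toward beads i+2 and i-2, proportional to their distance."""
    pos = state.positions
    F = np.zeros_like(pos)
    vec = pos[2:] - pos[:-2]
    same = state.chain_id[:-2] == state.chain_id[2:]
    pair = params.c4 * vec
    pair[~same] = 0.0
    F[:-2] += pair
    F[2:] -= pair
    return F


def condensin_force(
    state: ChainState,
    bonds: BondSet,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Hookean bond force between bonded condensin sites within 40 nm.

    A bonded pair farther apart than the interaction radius feels no force
    (the bond itself persists until its stochastic dissociation).
    """
    pos = state.positions
    F = np.zeros_like(pos)
    sites = state.condensin_sites
    site_set = set(int(s) for s in sites)
    for a, b in bonds.pairs():
        if a not in site_set or b not in site_set:
            raise ValueError(f"bond ({a}, {b}) does not join condensin sites")
        vec = pos[b] - pos[a]
        d = float(np.linalg.norm(vec))
        if d > params.attraction_radius or d < 1e-12:
            continue
        f = params.Kcondensin * (d - params.c5) * vec / d
        F[a] += f
        F[b] -= f
    return F


def total_force(
    state: ChainState,
    bonds: BondSet,
    params: SimulationParams,
    rng: np.random.Generator,
    entropic: Optional[np.ndarray] = None,
    decompose: bool = False,
):
    """Vector sum of the five force terms.

    ``entropic`` allows injecting a pre-drawn kick (the midpoint scheme
    reuses the step-start draw).  With ``decompose=True`` returns a dict of
    the individual terms alongside the sum.
    """
    if entropic is None:
        entropic = entropic_force(state, params, rng)
    terms = {
        "entropic": entropic,
        "tension": tension_force(state, params, rng),
        "repulsion": repulsion_force(state, params, rng),
        "attraction": attraction_force(state, params, rng),
        "condensin": condensin_force(state, bonds, params, rng),
    }
    F = sum(terms.values())
    if decompose:
        return F, terms
    return F
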