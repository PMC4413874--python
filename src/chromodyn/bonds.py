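"""Stochastic condensin crosslink bookkeeping (Type I / Type II rules).

Condensin is modelled as fixed binding-site beads that form pairwise
Hookean bonds whenever two free sites come within the 40 nm interaction
radius.  Each site holds at most one bond in the Type I model and at most
two in the Type II model.  An existing bond dissolves with probability
``p*dt`` per integration step; a freshly dissolved pair re-forms
automatically during a short window (3 steps) if still in range and both
sites still have capacity.

The update order per step is: dissociation draws, re-bond window
resolution, then new bond formation with sites traversed in random order
(avoiding index bias) and partners chosen uniformly among candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import numpy as np

from .chain import ChainState

__all__ = ["BondSet", "candidate_partners", "update_bonds"]

Pair = Tuple[int, int]


def _ordered(a: int, b: int) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass
class BondSet:
    """Current condensin crosslinks (unordered bead-index pairs) plus the
    per-pair re-formation window for recently broken bonds."""

    bonds: Set[Pair] = field(default_factory=set)
    cooldown: Dict[Pair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bonds = {_ordered(*p) for p in self.bonds}
        self.cooldown = {_ordered(*p): int(t) for p, t in self.cooldown.items()}

    def pairs(self) -> List[Pair]:
        return sorted(self.bonds)

    def degree(self, site: int) -> int:
        return sum(1 for a, b in self.bonds if site in (a, b))

    def degrees(self, sites: Iterable[int]) -> Dict[int, int]:
        deg = {int(s): 0 for s in sites}
        for a, b in self.bonds:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def partners(self, site: int) -> List[int]:
        return sorted(b if a == site else a for a, b in self.bonds if site in (a, b))

    def validate(self, state: ChainState, degree_cap: int) -> None:
        """Raise if any bond joins non-sites or exceeds the degree cap."""
        site_set = set(int(s) for s in state.condensin_sites)
        for a, b in self.bonds:
            if a not in site_set or b not in site_set:
                raise ValueError(f"bond ({a}, {b}) does not join condensin sites")
        for s, d in self.degrees(site_set).items():
            if d > degree_cap:
                raise ValueError(
                    f"site {s} holds {d} bonds, exceeding the cap of {degree_cap}"
                )

    def copy(self) -> "BondSet":
        return BondSet(bonds=set(self.bonds), cooldown=dict(self.cooldown))

    def __len__(self) -> int:
        return len(self.bonds)

    def __contains__(self, pair: Pair) -> bool:
        return _ordered(*pair) in self.bonds


def candidate_partners(
    state: ChainState,
    site: int,
    radius: float,
    bonds: BondSet | None = None,
) -> np.ndarray:
    """Condensin sites (any chain) within ``radius`` of ``site``, excluding
    itself and its current partners."""
    sites = state.condensin_sites
    if site not in sites:
        raise ValueError(f"bead {site} is not a condensin site")
    pos = state.positions
    d = np.linalg.norm(pos[sites] - pos[site], axis=1)
    near = sites[(d <= radius) & (sites != site)]
    if bonds is not None:
        current = set(bonds.partners(site))
        near = np.array([s for s in near if int(s) not in current], dtype=np.int64)
    return near


def update_bonds(
    state: ChainState,
    bonds: BondSet,
    params,
    rng: np.random.Generator,
    p_step: float | None = None,
) -> BondSet:
    """One stochastic update of the crosslink set.

    ``p_step`` overrides the per-step dissociation probability (defaults to
    ``params.p * params.effective_dt``).  Returns a new BondSet; the input
    is not modified.
    """
    if p_step is None:
        p_step = params.p * params.effective_dt
    cap = params.degree_cap
    radius = params.attraction_radius
    window = params.rebond_window
    out = bonds.copy()
    out.validate(state, cap)
    deg = out.degrees(state.condensin_sites)

    # 1. dissociation: independent uniform draw per bond
    for pair in sorted(out.bonds):
        if rng.random() < p_step:
            out.bonds.discard(pair)
            deg[pair[0]] -= 1
            deg[pair[1]] -= 1
            if window > 0:
                out.cooldown[pair] = window

    # 2. re-bond window: a recently broken pair re-forms if still in range
    #    and both sites retain capacity; otherwise its timer counts down
    pos = state.positions
    for pair in sorted(out.cooldown):
        a, b = pair
        t = out.cooldown[pair]
        if (
            deg.get(a, 0) < cap
            and deg.get(b, 0) < cap
            and np.linalg.norm(pos[a] - pos[b]) <= radius
        ):
            out.bonds.add(pair)
            deg[a] += 1
            deg[b] += 1
            del out.cooldown[pair]
        elif t <= 1:
            del out.cooldown[pair]
        else:
            out.cooldown[pair] = t - 1

    # 3. formation: random traversal order, uniform random partner choice
    sites = state.condensin_sites
    for idx in rng.permutation(len(sites)):
        s = int(sites[idx])
        if deg.get(s, 0) >= cap:
            continue
        near = candidate_partners(state, s, radius, out)
        near = [int(x) for x in near if deg.get(int(x), 0) < cap]
        while deg.get(s, 0) < cap and near:
            pick = near.pop(int(rng.integers(len(near))))
            if deg.get(pick, 0) >= cap:
                continue
            out.bonds.add(_ordered(s, pick))
            deg[s] += 1
            deg[pick] += 1

    out.validate(state, cap)
    return out
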