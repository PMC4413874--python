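"""Chain representation: bead positions, genomic mapping, condensin sites.

A chromatin chain is a sequence of 10 nm nucleosome beads; each bead stands
for ``bp_per_bead`` base pairs (150 bp by default, one nucleosome plus
linker), so the canonical 2000-bead chain spans ~300 kb.  Condensin binding
sites are a sorted subset of bead indices, placed by default on a regular
lattice approximating the ~10 kb spacing of condensin enrichment sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["ChainState", "build_chain", "assign_condensin_sites", "concatenate_chains"]


@dataclass
class ChainState:
    """Bead positions (nm) plus condensin-site indices for one or more chains."""

    positions: np.ndarray
    condensin_sites: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    chain_id: Optional[np.ndarray] = None
    bp_per_bead: float = 150.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        self.condensin_sites = np.asarray(self.condensin_sites, dtype=np.int64)
        n = self.positions.shape[0]
        if self.condensin_sites.size:
            if np.any(np.diff(self.condensin_sites) <= 0):
                raise ValueError("condensin_sites must be strictly increasing")
            if self.condensin_sites[0] < 0 or self.condensin_sites[-1] >= n:
                raise ValueError("condensin_sites out of bead range")
        if self.chain_id is None:
            self.chain_id = np.zeros(n, dtype=np.int64)
        else:
            self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
            if self.chain_id.shape != (n,):
                raise ValueError("chain_id must have one entry per bead")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(np.unique(self.chain_id).size)

    @property
    def total_bp(self) -> float:
        return self.n_beads * self.bp_per_bead

    def bead_to_bp(self, bead: int) -> float:
        """Genomic coordinate (bp) of a bead centre."""
        return bead * self.bp_per_bead

    def bp_to_bead(self, bp: float) -> int:
        """Bead index containing a genomic coordinate."""
        return int(round(bp / self.bp_per_bead))

    def consecutive_distances(self) -> np.ndarray:
        """Distances between consecutive beads, excluding inter-chain joints."""
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        same = self.chain_id[:-1] == self.chain_id[1:]
        return d[same]

    def default_markers(self, span_bp: float = 144_000.0) -> tuple[int, int]:
        """A marker bead pair ``span_bp`` apart, centred on the chain.

        The span is clipped to 80% of the chain when the chain is shorter
        than the requested separation (scaled-down runs).
        """
        span_beads = int(round(span_bp / self.bp_per_bead))
        span_beads = min(span_beads, int(0.8 * self.n_beads))
        mid = self.n_beads // 2
        a = mid - span_beads // 2
        b = a + span_beads
        return a, b

    def copy(self) -> "ChainState":
        return ChainState(
            positions=self.positions.copy(),
            condensin_sites=self.condensin_sites.copy(),
            chain_id=self.chain_id.copy(),
            bp_per_bead=self.bp_per_bead,
        )


def build_chain(
    n_beads: int,
    spacing: float = 15.0,
    bp_per_bead: float = 150.0,
    positions: Optional[np.ndarray] = None,
    condensin_sites: Optional[Sequence[int]] = None,
    site_interval_bp: Optional[float] = None,
) -> ChainState:
    """Construct a chain of ``n_beads`` nucleosomes.

    Without ``positions`` the chain is a straight line along z with
    consecutive spacing ``spacing`` (a debug geometry; production runs seed
    with :func:`chromodyn.initializer.hilbert_seed`).  Condensin sites may be
    given explicitly or placed on a regular lattice via ``site_interval_bp``.
    """
    if n_beads < 3:
        raise ValueError(f"n_beads must be >= 3, got {n_beads}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if positions is None:
        positions = np.zeros((n_beads, 3))
        positions[:, 2] = np.arange(n_beads) * spacing
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n_beads, 3):
            raise ValueError("supplied positions do not match n_beads")
    if condensin_sites is not None and site_interval_bp is not None:
        raise ValueError("give either condensin_sites or site_interval_bp, not both")
    if site_interval_bp is not None:
        sites = assign_condensin_sites(n_beads, bp_per_bead, site_interval_bp)
    elif condensin_sites is not None:
        sites = np.asarray(sorted(condensin_sites), dtype=np.int64)
    else:
        sites = np.empty(0, dtype=np.int64)
    return ChainState(positions=positions, condensin_sites=sites, bp_per_bead=bp_per_bead)


def assign_condensin_sites(
    n_beads: int, bp_per_bead: float, interval_bp: float
) -> np.ndarray:
    """Evenly spaced condensin-site bead indices, ~one per ``interval_bp``.

    Sites sit on a regular lattice starting half an interval from the chain
    start, so no site falls within half an interval of either end.
    """
    if interval_bp < bp_per_bead:
        raise ValueError(
            f"site interval {interval_bp} bp is below the chain resolution "
            f"of {bp_per_bead} bp per bead"
        )
    spacing_beads = max(1, int(round(interval_bp / bp_per_bead)))
    count = max(1, int(round(n_beads / spacing_beads)))
    while (count - 1) * spacing_beads >= n_beads:
        count -= 1
    offset = (n_beads - 1 - (count - 1) * spacing_beads) // 2
    return offset + np.arange(count, dtype=np.int64) * spacing_beads


def concatenate_chains(*chains: ChainState) -> ChainState:
    """Merge several chains into one multi-chain state.

    Bead and site indices of later chains are offset; chain identity is
    preserved in ``chain_id`` so linkers never bridge two chains.
    """
    if len(chains) < 1:
        raise ValueError("at least one chain required")
    bpb = chains[0].bp_per_bead
    positions, sites, cids = [], [], []
    offset = 0
    for k, ch in enumerate(chains):
        if ch.bp_per_bead != bpb:
            raise ValueError("all chains must share bp_per_bead")
        positions.append(ch.positions)
        sites.append(ch.condensin_sites + offset)
        cids.append(np.full(ch.n_beads, k, dtype=np.int64))
        offset += ch.n_beads
    return ChainState(
        positions=np.vstack(positions),
        condensin_sites=np.concatenate(sites),
        chain_id=np.concatenate(cids),
        bp_per_bead=bpb,
    )
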