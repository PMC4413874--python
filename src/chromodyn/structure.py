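"""Architecture-level analyses of simulated chromosomes.

Distance maps and rosette/web classification of condensin binding sites,
simulated 4C viewpoint profiles with long-range interaction fractions,
occupied-volume estimation on a cubic grid, interchain contact counts for
multi-chain runs, and the orientational-correlation persistence length.

A *rosette* is a cluster of more than two condensin binding sites within
the condensin interaction radius (40 nm, single linkage); sites outside
rosettes form the dynamic *web*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree, distance_matrix

from .chain import ChainState
from .trajectory import Trajectory

__all__ = [
    "site_distance_map",
    "rosette_clusters",
    "RosetteRecord",
    "RosetteStats",
    "rosette_stats",
    "ViewpointProfile",
    "viewpoint_profile",
    "default_viewpoints",
    "long_range_fraction",
    "occupied_volume",
    "project_genome_volume",
    "interchain_contacts",
    "PersistenceResult",
    "persistence_length",
]


def site_distance_map(
    state: ChainState, sites: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Pairwise Euclidean distances (nm) between condensin sites."""
    if sites is None:
        sites = state.condensin_sites
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size < 2:
        raise ValueError("a distance map needs at least 2 sites")
    pos = state.positions[sites]
    return distance_matrix(pos, pos)


def rosette_clusters(
    state: ChainState,
    sites: Optional[Sequence[int]] = None,
    radius: float = 40.0,
    min_size: int = 3,
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Single-linkage clusters of condensin sites at linkage <= radius.

    Returns ``(rosettes, web)``: clusters with at least ``min_size``
    members ("more than two sites in proximity") and the remaining
    clusters.  Together they partition the sites.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if sites is None:
        sites = state.condensin_sites
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        return [], []
    pos = state.positions[sites]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = sites.size
    if pairs.size:
        data = np.ones(len(pairs), dtype=bool)
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n), dtype=bool)
    _, labels = connected_components(adj, directed=False)
    rosettes, web = [], []
    for lab in np.unique(labels):
        members = sites[labels == lab]
        (rosettes if members.size >= min_size else web).append(members)
    return rosettes, web


@dataclass
class RosetteRecord:
    """One rosette tracked across frames."""

    members: frozenset
    birth_frame: int
    death_frame: int  # last frame alive (inclusive)
    sizes: List[int] = field(default_factory=list)

    @property
    def lifespan_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else 0.0


@dataclass
class RosetteStats:
    """Ensemble summary of rosette structures over a trajectory."""

    percent_sites_in_rosettes: float
    mean_lifespan_seconds: float
    mean_size: float
    records: List[RosetteRecord]


def rosette_stats(
    traj: Trajectory,
    radius: float = 40.0,
    min_size: int = 3,
    overlap: float = 0.5,
    discard_frames: int = 0,
) -> RosetteStats:
    """Track rosettes across frames and summarise them.

    Identity across consecutive frames requires member overlap
    ``|A & B| / max(|A|, |B|) >= overlap``.  Lifespans are reported in
    in-vivo seconds (frames alive x seconds per frame); the percentage is
    the mean fraction of condensin sites belonging to rosettes.
    """
    fs = traj.frame_seconds
    if traj.n_frames - discard_frames >= 2 and fs <= 0:
        warnings.warn("frame stride too coarse to resolve lifetimes")
    records: List[RosetteRecord] = []
    live: List[RosetteRecord] = []
    fractions = []
    nsites = max(1, traj.sites.size)
    for f in range(discard_frames, traj.n_frames):
        state = traj.state(f)
        rosettes, _ = rosette_clusters(state, radius=radius, min_size=min_size)
        fractions.append(sum(len(r) for r in rosettes) / nsites)
        current = [frozenset(int(x) for x in r) for r in rosettes]
        matched: List[RosetteRecord] = []
        for mem in current:
            best, best_ov = None, 0.0
            for rec in live:
                ov = len(mem & rec.members) / max(len(mem), len(rec.members))
                if ov > best_ov:
                    best, best_ov = rec, ov
            if best is not None and best_ov >= overlap and best not in matched:
                best.members = mem
                best.death_frame = f
                best.sizes.append(len(mem))
                matched.append(best)
            else:
                rec = RosetteRecord(mem, birth_frame=f, death_frame=f, sizes=[len(mem)])
                records.append(rec)
                matched.append(rec)
        live = matched
    if records:
        mean_life = float(np.mean([r.lifespan_frames for r in records])) * fs
        mean_size = float(np.mean([r.mean_size for r in records]))
    else:
        mean_life = 0.0
        mean_size = 0.0
    return RosetteStats(
        percent_sites_in_rosettes=100.0 * float(np.mean(fractions)) if fractions else 0.0,
        mean_lifespan_seconds=mean_life,
        mean_size=mean_size,
        records=records,
    )


@dataclass
class ViewpointProfile:
    """Normalised contact frequencies of one viewpoint against all beads."""

    viewpoint: int
    frequencies: np.ndarray  # per bead, sums to 1, self excluded
    genomic_bp: np.ndarray  # genomic coordinate of each bead (bp)
    contact_radius: float
    bp_per_bead: float

    def long_range_fraction(self, threshold_bp: float = 100_000.0) -> float:
        return long_range_fraction(self, threshold_bp)


def viewpoint_profile(
    traj: Trajectory,
    viewpoint: int,
    contact_radius: float = 40.0,
    discard_frames: int = 0,
    sites_only: bool = False,
) -> ViewpointProfile:
    """Simulated 4C profile: fraction of contacts each bead contributes.

    A contact is a frame in which a bead lies within ``contact_radius`` of
    the viewpoint bead.  Frequencies are normalised to all contacts (self
    excluded).  ``sites_only`` restricts both viewpoint partners to
    condensin sites.
    """
    n = traj.n_beads
    if not 0 <= viewpoint < n:
        raise IndexError(f"viewpoint {viewpoint} out of range")
    if contact_radius <= 0:
        raise ValueError("contact_radius must be positive")
    frames = traj.frames[discard_frames:].astype(float)
    if frames.shape[0] == 0:
        raise ValueError("no frames to analyse")
    d = np.linalg.norm(frames - frames[:, viewpoint][:, None, :], axis=2)
    counts = (d <= contact_radius).sum(axis=0).astype(float)
    counts[viewpoint] = 0.0
    if sites_only:
        mask = np.zeros(n, dtype=bool)
        mask[traj.sites] = True
        counts[~mask] = 0.0
    total = counts.sum()
    if total == 0:
        raise ValueError("viewpoint registered no contacts")
    return ViewpointProfile(
        viewpoint=viewpoint,
        frequencies=counts / total,
        genomic_bp=np.arange(n) * traj.bp_per_bead,
        contact_radius=contact_radius,
        bp_per_bead=traj.bp_per_bead,
    )


def default_viewpoints(
    n_beads: int, bp_per_bead: float = 150.0, n_viewpoints: int = 6,
    end_exclusion_bp: float = 50_000.0,
) -> np.ndarray:
    """Evenly spaced viewpoints excluding a margin at each chain end."""
    margin = min(int(end_exclusion_bp / bp_per_bead), n_beads // 4)
    return np.linspace(margin, n_beads - 1 - margin, n_viewpoints).astype(int)


def long_range_fraction(profile: ViewpointProfile, threshold_bp: float = 100_000.0) -> float:
    """Percentage of normalised contacts beyond ``threshold_bp`` from the
    viewpoint (genomic distance)."""
    offsets = np.abs(profile.genomic_bp - profile.genomic_bp[profile.viewpoint])
    if threshold_bp >= offsets.max():
        warnings.warn(
            f"threshold {threshold_bp} bp is beyond the chain span; fraction is 0"
        )
        return 0.0
    return 100.0 * float(profile.frequencies[offsets > threshold_bp].sum())


def occupied_volume(
    state: ChainState | np.ndarray, grid_edge: float = 50.0
) -> float:
    """Volume (um^3) of grid cells containing at least one bead centre.

    The chain's bounding box is partitioned into cubes of ``grid_edge`` nm;
    the occupied-cell count times the cell volume approximates the
    chromosome volume (50 nm default, matching the local persistence
    length of the simulated chain).
    """
    if grid_edge <= 0:
        raise ValueError("grid_edge must be positive")
    pos = state.positions if isinstance(state, ChainState) else np.asarray(state, float)
    cells = np.floor(pos / grid_edge).astype(np.int64)
    occupied = np.unique(cells, axis=0).shape[0]
    return occupied * (grid_edge * 1e-3) ** 3


def project_genome_volume(per_chromosome_volume: float, factor: float = 40.0) -> float:
    """Scale a single-chromosome volume to the whole genome (12 Mb / 300 kb
    = 40 by default)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return per_chromosome_volume * factor


def interchain_contacts(
    state_or_traj: ChainState | Trajectory,
    radius: float = 40.0,
    discard_frames: int = 0,
) -> float:
    """Number of bead pairs on different chains within ``radius``.

    For a trajectory, the count is averaged over frames.
    """
    if isinstance(state_or_traj, Trajectory):
        traj = state_or_traj
        vals = [
            interchain_contacts(traj.state(k), radius)
            for k in range(discard_frames, traj.n_frames)
        ]
        return float(np.mean(vals))
    state = state_or_traj
    if state.n_chains < 2:
        raise ValueError("interchain contacts need at least two chains")
    tree = cKDTree(state.positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return 0.0
    return float((state.chain_id[pairs[:, 0]] != state.chain_id[pairs[:, 1]]).sum())


@dataclass
class PersistenceResult:
    """Orientational correlation function and the persistence length."""

    contour_nm: np.ndarray  # contour separations L'
    correlation: np.ndarray  # K_or(L')
    lp_nm: float  # integral up to the cutoff
    cutoff_bp: float

    def lp_at(self, cutoff_bp: float, bp_per_nm: float) -> float:
        """Lp from the partial sum up to another genomic cutoff."""
        cutoff_nm = cutoff_bp / bp_per_nm
        if len(self.contour_nm) < 2:
            return 0.0
        bond = self.contour_nm[1] - self.contour_nm[0]
        mask = self.contour_nm < cutoff_nm
        return float(self.correlation[mask].sum() * bond)


def persistence_length(
    structures: Sequence[ChainState] | Trajectory,
    cutoff_bp: float = 100_000.0,
    discard_frames: int = 0,
) -> PersistenceResult:
    """Persistence length from the tangent orientational correlation.

    Unit tangents are consecutive-bead vectors; ``K_or(L')`` averages
    ``u(L) . u(L + L')`` over all pairs separated by contour distance
    ``L'`` and over all structures; ``Lp`` is the numerical integral
    (left-rectangle sum) of ``K_or`` up to the genomic-distance cutoff.
    For a rigid rod the result equals the integration cutoff length; for
    a freely jointed chain it reduces to ``b / (1 - <cos theta>)``.
    """
    if isinstance(structures, Trajectory):
        traj = structures
        states = [traj.state(k) for k in range(discard_frames, traj.n_frames)]
    else:
        states = list(structures)
    if not states:
        raise ValueError("no structures supplied")
    if len(states) < 5:
        warnings.warn("few structures; persistence estimate will be noisy")
    bp_per_bead = states[0].bp_per_bead
    n = states[0].n_beads
    bond_nm = float(np.mean([s.consecutive_distances().mean() for s in states]))
    bp_per_nm = bp_per_bead / bond_nm
    max_lag = min(n - 2, int(round(cutoff_bp / bp_per_bead)))
    acc = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    for s in states:
        vec = np.diff(s.positions, axis=0)
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        u = vec / np.where(norms < 1e-12, 1.0, norms)
        for lag in range(0, max_lag + 1):
            if lag == 0:
                acc[0] += u.shape[0]
                cnt[0] += u.shape[0]
            else:
                dots = (u[:-lag] * u[lag:]).sum(axis=1)
                acc[lag] += dots.sum()
                cnt[lag] += dots.size
    kor = acc / np.maximum(cnt, 1)
    contour = np.arange(max_lag + 1) * bond_nm
    # left-rectangle sum over [0, cutoff): reduces to the geometric-series
    # closed form b/(1 - <cos theta>) for a freely jointed chain and to the
    # cutoff length for a rigid rod
    lp = float(kor[:max_lag].sum() * bond_nm)
    return PersistenceResult(
        contour_nm=contour, correlation=kor, lp_nm=lp, cutoff_bp=cutoff_bp
    )
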