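"""Trajectory persistence and standard-format export.

Trajectories are stored as HDF5 (chunked binary arrays) with a JSON text
header carrying the full configuration, seed and schema version, so a file
is self-describing and round trips losslessly.  Single frames export to
XYZ and PDB for external viewers; 4C viewpoint profiles export to
bedGraph-like text on a synthetic chromosome coordinate system; tabular
observables export as TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .chain import ChainState
from .structure import ViewpointProfile
from .trajectory import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "TrajectoryFormatError",
    "export_frame_xyz",
    "read_frame_xyz",
    "export_frame_pdb",
    "export_profile_bedgraph",
    "export_force_decomposition",
]

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class TrajectoryFormatError(RuntimeError):
    """The file is not a readable chromodyn trajectory (corruption,
    truncation or schema mismatch)."""


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    """Write a trajectory to HDF5 with full provenance."""
    import h5py

    header = {
        "schema_version": SCHEMA_VERSION,
        "seconds_per_step": traj.seconds_per_step,
        "bp_per_bead": traj.bp_per_bead,
        "params": traj.params,
        "seed": traj.seed,
        "schedule": [list(x) for x in traj.schedule],
        "markers": list(traj.markers) if traj.markers is not None else None,
    }
    with h5py.File(path, "w") as f:
        f.attrs["chromodyn_header"] = json.dumps(header)
        f.create_dataset("frames", data=traj.frames, compression="gzip", shuffle=True)
        f.create_dataset("step_index", data=traj.step_index)
        f.create_dataset("sites", data=traj.sites)
        f.create_dataset("chain_id", data=traj.chain_id)
        if traj.bonds is not None:
            f.create_dataset("bonds", data=traj.bonds, compression="gzip")
        if traj.bond_counts is not None:
            f.create_dataset("bond_counts", data=traj.bond_counts)


def read_trajectory(path: PathLike) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises :class:`TrajectoryFormatError` on corrupted or incompatible
    files rather than propagating low-level errors.
    """
    import h5py

    try:
        with h5py.File(path, "r") as f:
            raw = f.attrs.get("chromodyn_header")
            if raw is None:
                raise TrajectoryFormatError(f"{path}: missing chromodyn header")
            try:
                header = json.loads(raw)
            except json.JSONDecodeError as e:
                raise TrajectoryFormatError(f"{path}: unreadable header: {e}") from e
            version = header.get("schema_version")
            if version != SCHEMA_VERSION:
                raise TrajectoryFormatError(
                    f"{path}: schema version {version} not supported "
                    f"(expected {SCHEMA_VERSION})"
                )
            try:
                frames = f["frames"][...]
                step_index = f["step_index"][...]
                sites = f["sites"][...]
                chain_id = f["chain_id"][...]
                bonds = f["bonds"][...] if "bonds" in f else None
                bond_counts = f["bond_counts"][...] if "bond_counts" in f else None
            except KeyError as e:
                raise TrajectoryFormatError(f"{path}: missing dataset {e}") from e
    except OSError as e:
        raise TrajectoryFormatError(f"{path}: not a readable HDF5 file: {e}") from e
    markers = header.get("markers")
    return Trajectory(
        frames=frames,
        step_index=step_index,
        seconds_per_step=header["seconds_per_step"],
        sites=sites,
        chain_id=chain_id,
        bp_per_bead=header["bp_per_bead"],
        bonds=bonds,
        bond_counts=bond_counts,
        params=header.get("params", {}),
        seed=header.get("seed", 0),
        schedule=[tuple(x) for x in header.get("schedule", [])],
        markers=tuple(markers) if markers else None,
    )


def export_frame_xyz(state: ChainState, path: PathLike, comment: str = "") -> None:
    """One pseudo-atom per bead in XYZ format (coordinates in nm).

    Condensin sites are written with element ``O``, other beads ``C``;
    multi-chain states are concatenated in bead order.
    """
    site_set = set(int(s) for s in state.condensin_sites)
    lines = [str(state.n_beads), comment or "chromodyn frame (nm)"]
    for i, (x, y, z) in enumerate(state.positions):
        el = "O" if i in site_set else "C"
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_frame_xyz(path: PathLike) -> ChainState:
    """Read back an XYZ frame written by :func:`export_frame_xyz`."""
    text = Path(path).read_text().strip().splitlines()
    try:
        n = int(text[0])
        rows = [line.split() for line in text[2 : 2 + n]]
        positions = np.array([[float(v) for v in r[1:4]] for r in rows])
        sites = np.array(
            [i for i, r in enumerate(rows) if r[0] == "O"], dtype=np.int64
        )
    except (ValueError, IndexError) as e:
        raise TrajectoryFormatError(f"{path}: malformed XYZ file: {e}") from e
    if positions.shape[0] != n:
        raise TrajectoryFormatError(f"{path}: truncated XYZ file")
    return ChainState(positions=positions, condensin_sites=sites)


def export_frame_pdb(state: ChainState, path: PathLike) -> None:
    """One pseudo-atom per bead as PDB (coordinates in Angstrom = nm * 10).

    Beads are CA atoms; condensin sites get residue name ``CND`` (others
    ``NUC``); each chromatin chain gets its own chain identifier.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = state.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(state.positions, dtype=np.float32) * 10.0
    site_set = set(int(s) for s in state.condensin_sites)
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    arr.chain_id = np.array(
        [chain_letters[int(c) % len(chain_letters)] for c in state.chain_id]
    )
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(
        ["CND" if i in site_set else "NUC" for i in range(n)]
    )
    arr.atom_name = np.full(n, "CA")
    arr.element = np.array(["O" if i in site_set else "C" for i in range(n)])
    arr.hetero = np.full(n, True)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def export_profile_bedgraph(
    profile: ViewpointProfile, path: PathLike, chrom: str = "chrV-sim"
) -> None:
    """Write a 4C viewpoint profile as bedGraph-like text.

    One row per bead: chrom, start (bp), end (bp), normalised contact
    frequency.  The viewpoint bead itself (frequency 0) is included so the
    file covers the whole synthetic chromosome."""
    bpb = profile.bp_per_bead
    with open(path, "w") as f:
        f.write(
            f"track type=bedGraph name=viewpoint_{profile.viewpoint} "
            f"description=\"simulated 4C, contact radius "
            f"{profile.contact_radius} nm\"\n"
        )
        for i, freq in enumerate(profile.frequencies):
            start = int(round(i * bpb))
            end = int(round((i + 1) * bpb))
            f.write(f"{chrom}\t{start}\t{end}\t{freq:.6g}\n")


def export_force_decomposition(state, bonds, params, path: PathLike, rng=None) -> None:
    """Dump the per-bead force terms of one frame as tidy TSV.

    One row per (bead, term) with the force components in pN; the entropic
    term is a fresh draw unless ``rng`` is seeded for reproducibility.
    """
    import numpy as _np
    import pandas as pd

    from .forces import total_force

    if rng is None:
        rng = _np.random.default_rng(0)
    _, terms = total_force(state, bonds, params, rng, decompose=True)
    rows = []
    for name, F in terms.items():
        for i in range(state.n_beads):
            rows.append(
                {"bead": i, "term": name,
                 "fx_pN": F[i, 0], "fy_pN": F[i, 1], "fz_pN": F[i, 2]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
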