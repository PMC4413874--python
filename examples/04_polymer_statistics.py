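"""Polymer-physics characterisation: kurtosis, persistence length, volume.

On an equilibrated chain this computes (1) the Pearson kurtosis of
inter-locus distance distributions at several genomic separations — a
shape fingerprint that distinguishes polymer models (Gaussian would be
K=3; loop polymers sit below), (2) the persistence length from the
tangent orientational correlation function at increasing genomic
cutoffs, and (3) the occupied volume on a 50 nm grid with its projection
to the whole genome.
"""

import numpy as np

from chromodyn.observables import kurtosis
from chromodyn.protocols import local_equilibrium_run
from chromodyn.structure import occupied_volume, persistence_length, project_genome_volume

traj = local_equilibrium_run(seed=3)
frames = traj.frames[120:].astype(float)

print("kurtosis of inter-locus distances:")
for sep in (20, 50, 100, 150):
    d = np.linalg.norm(frames[:, sep:] - frames[:, :-sep], axis=2).ravel()
    print(f"  {sep * traj.bp_per_bead / 1000:5.1f} kb separation: K = {kurtosis(d):.2f}")

states = [traj.state(k) for k in range(120, traj.n_frames, 20)]
res = persistence_length(states, cutoff_bp=40_000.0)
bond = res.contour_nm[1]
print("persistence length (orientational correlation integral):")
for cutoff_kb in (3, 10, 40):
    lp = res.lp_at(cutoff_kb * 1000.0, traj.bp_per_bead / bond)
    print(f"  cutoff {cutoff_kb:3d} kb: Lp = {lp:5.1f} nm")

vols = [occupied_volume(frames[k]) for k in range(0, len(frames), 10)]
per_chain = float(np.mean(vols))
chromosome = per_chain * 2000 / traj.n_beads  # project to the 300 kb chain
print(f"occupied volume ({traj.n_beads} beads): {per_chain:.2e} um^3")
print(f"  projected to a 2000-bead chromosome: {chromosome:.2e} um^3")
print(f"  x40 genome projection:               {project_genome_volume(chromosome):.2f} um^3")
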