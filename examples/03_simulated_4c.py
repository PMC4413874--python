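"""Simulated 4C: viewpoint contact profiles and long-range interactions.

Computes distance-thresholded contact frequencies of chosen viewpoint
beads against all other beads over an equilibrated trajectory — the
computational analogue of a circularised chromosome conformation capture
(4C) profile — and the percentage of contacts beyond a genomic distance
threshold.  Profiles are written as bedGraph-like text for genome-browser
style plotting.
"""

from chromodyn.io import export_profile_bedgraph
from chromodyn.protocols import scaled_condensation_run
from chromodyn.structure import default_viewpoints, long_range_fraction, viewpoint_profile

traj = scaled_condensation_run("type2", seed=1).trajectory
threshold_bp = 3000.0

for vp in default_viewpoints(traj.n_beads, traj.bp_per_bead, n_viewpoints=3):
    prof = viewpoint_profile(traj, int(vp), contact_radius=40.0, discard_frames=150)
    frac = long_range_fraction(prof, threshold_bp)
    print(
        f"viewpoint bead {vp:3d} ({vp * traj.bp_per_bead / 1000:.1f} kb): "
        f"{frac:5.1f}% of contacts beyond {threshold_bp / 1000:.0f} kb"
    )

prof = viewpoint_profile(traj, int(default_viewpoints(traj.n_beads)[0]),
                         discard_frames=150)
export_profile_bedgraph(prof, "viewpoint.bedgraph")
print("\nwrote viewpoint.bedgraph (chrom, start, end, normalised frequency)")
print("frequencies are normalised to all contacts of the viewpoint; the")
print("long-range share rises when crosslinks fold distant sites together")
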