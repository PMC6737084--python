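"""Helix-coupling analysis on a synthetic correlated trajectory.

Generates a 20-residue Cα trajectory in which two labelled segments ("H3"
and "H12") move with a cross-correlation of 0.8, estimates the Pearson
cross-correlation map, and compresses it into noise-filtered coupling
scores.  A strongly positive H3–H12 score is the signature the analysis is
designed to detect: in the mutant receptor it indicates helix 12 moving in
lockstep with the helix 3/5 groove, i.e. an agonist-like (activated) state.
"""

import numpy as np

from ercoupler import (
    BlockCorrelationSpec, Segment, SegmentMap, covariance_matrix,
    cross_correlation_matrix, generate_correlated_trajectory, per_residue_profile,
    segment_correlation_score, select,
)

segments = SegmentMap([Segment("H3", "A", 1, 6), Segment("H12", "A", 13, 18)])
spec = BlockCorrelationSpec(
    segments=segments, n_residues=20, within_block_rho=0.85,
    cross_block_rho={("H3", "H12"): 0.8}, n_frames=8000, noise_sd=0.5, seed=42,
)
traj, true_cc = generate_correlated_trajectory(spec)
print(f"synthetic trajectory: {traj.n_frames} frames × {traj.n_atoms} Cα atoms")

sel = select(traj.topology, name="CA")
cc = cross_correlation_matrix(covariance_matrix(traj, sel))
block = cc.values[0:6, 12:18]
print(f"estimated H3–H12 block CC: {block.mean():.3f} (generator truth 0.80)")

table = segment_correlation_score(cc, traj.topology, segments, threshold=0.6)
print("\ncoupling scores (|CC| >= 0.6, correlation-density normalized):")
print(table.entries.to_string(index=False))

profile = per_residue_profile(cc, traj.topology, "H12", segments, threshold=0.6)
coupled = profile[profile.cc_sum != 0]
print(f"\nresidues coupled to H12: {len(coupled)} of {len(profile)}")
print("a nonzero H3–H12 score flags correlated helix motion; on a receptor")
print("trajectory this is the activation signature an antagonist should remove")
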