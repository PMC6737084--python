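"""Conformational clustering and H-bond persistence on synthetic systems.

Builds a trajectory hopping between three reference conformations, recovers
them with greedy RMSD-neighbor clustering, then measures the occupancy of a
donor–H···acceptor contact engineered to be formed in 37% of frames — the
kind of persistence statistic used to rank ligand anchor points (L346,
E419, K529) in a binding cavity.
"""

import numpy as np

from ercoupler import (
    HBondCriteria, Trajectory, daura_cluster, generate_hbond_system,
    hbond_occupancy, select,
)
from ercoupler.synthetic import _ca_topology

rng = np.random.default_rng(11)
top = _ca_topology(8)
conformers = [rng.random((8, 3)) * 8 for _ in range(3)]
labels = rng.integers(0, 3, size=30)
frames = np.array([conformers[k] + 0.3 * rng.standard_normal((8, 3)) for k in labels])
traj = Trajectory(top, frames)

result = daura_cluster(traj, select(top, name="CA"), cutoff=1.5)
print(f"clusters found: {result.n_clusters} (true conformers: 3)")
print(f"cluster sizes: {list(result.sizes())} — emitted in decreasing size order")
print(f"centroid frames: {result.centroids}")

hb_traj, truth = generate_hbond_system(100, bonded_frame_fraction=0.37, seed=5)
table = hbond_occupancy(
    hb_traj, select(hb_traj.topology, element="N"),
    select(hb_traj.topology, element="O"), HBondCriteria(3.5, 120.0),
)
print(f"\nH-bond occupancy: {table.iloc[0]['occupancy']:.2f} "
      f"(designed {truth.iloc[0]['occupancy']:.2f})")
print(f"mean D···A distance in bonded frames: {table.iloc[0]['mean_distance']:.2f} Å")
print("occupancy near 1 marks a persistent anchor; low values are transient contacts")
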