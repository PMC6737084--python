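"""RMSD, greedy RMSD-neighbor (Daura) clustering, and H-bond persistence.

These are the bread-and-butter trajectory diagnostics used to characterise
how a ligand anchors in the binding cavity: which conformational families
the complex visits, and which donor–acceptor contacts (e.g. to L346, E419,
K529) persist over the sampled time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import AtomSelection, Trajectory

__all__ = [
    "ClusterResult",
    "HBondCriteria",
    "rmsd",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "hbond_occupancy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond rule: D···A distance and D–H···A angle.

    Defaults (3.5 Å, 120°) are common MD practice; every report records the
    criteria it used, since occupancies are only comparable under one rule.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass
class ClusterResult:
    """Greedy-clustering output: frame assignments and per-cluster centroids.

    Clusters are numbered 0, 1, … in the order they were extracted, which by
    construction is also non-increasing size order.
    """

    assignments: np.ndarray  # frame -> cluster id
    centroids: list[int]  # cluster id -> centroid frame index
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster_id)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.assignments.size),
                "cluster": self.assignments,
                "is_centroid": np.isin(np.arange(self.assignments.size), self.centroids),
            }
        )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: AtomSelection | None = None,
    fit: bool = True,
) -> float:
    """Root-mean-square deviation between two frames, in Å.

    With ``fit=True`` the optimal rigid superposition (rotation +
    translation) of b onto a is applied first.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        idx = selection.indices()
        if idx.size == 0:
            raise ValueError("empty selection")
        a, b = a[idx], b[idx]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"frames must share an (n, 3) shape; got {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one atom")
    if fit:
        ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(ac, bc)
        # evaluate the residual on the rotated coordinates directly: the
        # eigenvalue-based residual loses precision for near-rigid pairs
        b = rot.apply(bc)
        a = ac
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd_matrix(traj: Trajectory, selection: AtomSelection) -> np.ndarray:
    """Symmetric matrix of pairwise fitted RMSDs over a selection."""
    idx = selection.indices()
    coords = traj.coordinates[:, idx, :]
    n = traj.n_frames
    mat = np.zeros((n, n))
    centered = coords - coords.mean(axis=1, keepdims=True)
    for i in range(n):
        for j in range(i + 1, n):
            rot, _ = Rotation.align_vectors(centered[i], centered[j])
            d = rot.apply(centered[j]) - centered[i]
            mat[i, j] = mat[j, i] = np.sqrt((d**2).sum(axis=1).mean())
    return mat


# ---------------------------------------------------------------------------
# Daura clustering
# ---------------------------------------------------------------------------

def daura_cluster(
    traj: Trajectory, selection: AtomSelection, cutoff: float
) -> ClusterResult:
    """Greedy RMSD-neighbor clustering (GROMOS style).

    Repeatedly take the frame with the most unassigned neighbors within
    ``cutoff`` (fitted RMSD), emit it as a centroid with its neighbors as a
    cluster, remove them, and iterate until every frame is assigned.  When
    two frames tie on neighbor count the lowest frame index wins, making the
    result deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = pairwise_rmsd_matrix(traj, selection)
    n = dist.shape[0]
    neighbor = dist <= cutoff  # includes self on the diagonal
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
        members = np.nonzero(neighbor[center] & remaining)[0]
        cid = len(centroids)
        assignments[members] = cid
        centroids.append(center)
        remaining[members] = False
    return ClusterResult(assignments, centroids, float(cutoff))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

#: maximum covalent D–H distance used to attach hydrogens to donor heavy atoms
COVALENT_H_CUTOFF = 1.2


def _attached_hydrogens(traj: Trajectory, donor_idx: int) -> list[int]:
    """Hydrogen atoms within covalent range of a donor in the first frame."""
    top = traj.topology
    h_mask = top.column("is_hydrogen")
    d = traj.coordinates[0, donor_idx]
    dist = np.linalg.norm(traj.coordinates[0] - d, axis=1)
    return [int(i) for i in np.nonzero(h_mask & (dist <= COVALENT_H_CUTOFF))[0]]


def hbond_occupancy(
    traj: Trajectory,
    donors: AtomSelection,
    acceptors: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
    report_floor: float = 0.0,
) -> pd.DataFrame:
    """Occupancy of every donor–H···acceptor triple across the trajectory.

    A triple counts as bonded in a frame iff the donor–acceptor distance is
    ≤ ``criteria.max_da_distance`` and the donor–H–acceptor angle is
    ≥ ``criteria.min_dha_angle``.  Occupancy is the bonded-frame fraction.
    Donors with no covalently attached hydrogen are skipped with a warning.
    Triples never satisfying the distance cut, or below ``report_floor``
    occupancy, are omitted from the table.
    """
    top = traj.topology
    records = []
    acc_idx = acceptors.indices()
    cos_min = np.cos(np.deg2rad(criteria.min_dha_angle))
    for d_idx in donors.indices():
        hydrogens = _attached_hydrogens(traj, int(d_idx))
        if not hydrogens:
            log.warning(
                "donor %s (atom %d) has no covalent hydrogen; skipped",
                top.atoms[int(d_idx)].atom_name, int(d_idx) + 1,
            )
            continue
        for h_idx in hydrogens:
            for a_idx in acc_idx:
                if int(a_idx) in (int(d_idx), h_idx):
                    continue
                d = traj.coordinates[:, int(d_idx), :]
                h = traj.coordinates[:, h_idx, :]
                a = traj.coordinates[:, int(a_idx), :]
                da = np.linalg.norm(a - d, axis=1)
                # D–H···A angle at the hydrogen: vectors H→D and H→A
                v1 = d - h
                v2 = a - h
                cosang = np.sum(v1 * v2, axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                )
                bonded = (da <= criteria.max_da_distance) & (cosang <= cos_min)
                occ = float(bonded.mean())
                if occ == 0.0 or occ < report_floor:
                    continue
                records.append(
                    {
                        "donor_atom": int(d_idx) + 1,
                        "hydrogen_atom": h_idx + 1,
                        "acceptor_atom": int(a_idx) + 1,
                        "occupancy": occ,
                        "mean_distance": float(da[bonded].mean()),
                    }
                )
    df = pd.DataFrame.from_records(
        records,
        columns=["donor_atom", "hydrogen_atom", "acceptor_atom", "occupancy", "mean_distance"],
    )
    df.attrs["criteria"] = criteria
    return df.sort_values("occupancy", ascending=False).reset_index(drop=True)
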