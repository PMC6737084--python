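import numpy as np
import pytest

from ercoupler.core import Atom, Segment, SegmentMap, Topology, Trajectory


@pytest.fixture
def tripeptide_topology() -> Topology:
    """Three-residue backbone with N, CA, C and an amide hydrogen each."""
    atoms = []
    aid = 1
    for resi, resn in enumerate(["ALA", "GLY", "SER"], start=1):
        for name, elem in [("N", "N"), ("H", "H"), ("CA", "C"), ("C", "C"), ("O", "O")]:
            atoms.append(
                Atom(aid, name, elem, resi, resn, "A", elem == "H")
            )
            aid += 1
    return Topology(atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture
def random_trajectory(tripeptide_topology, rng) -> Trajectory:
    coords = 10.0 * rng.random((5, len(tripeptide_topology), 3))
    return Trajectory(tripeptide_topology, coords)


@pytest.fixture
def two_segment_map() -> SegmentMap:
    return SegmentMap([Segment("H3", "A", 1, 1), Segment("H12", "A", 3, 3)])


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    return (
        Rotation.random(rng=rng).as_matrix(),
        rng.uniform(-20.0, 20.0, size=3),
    )


def quaternion_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent superposition oracle via the Horn quaternion method.

    Builds the 4×4 key matrix from the correlation of the centred
    coordinate sets; the largest eigenvalue gives the minimal residual.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = b.T @ a  # correlation of mobile (b) against reference (a)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))
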