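"""Seeded generators for every input class the pipeline consumes.

Each generator returns machine-readable ground truth next to the data, so
every analysis stage can be validated with no external downloads: correlated
Cα trajectories with a known block cross-correlation structure, donor–H–
acceptor systems with an exactly controlled H-bond occupancy, compound
tables with exactly determined filter tallies, and toy potentials with
closed-form barriers for the metadynamics engine.

The generators emulate the statistical structure the analyses estimate, not
realistic force-field dynamics: the correlated trajectories are Gaussian
displacements on a rigid helical backbone, and the toy landscapes are low-
dimensional stand-ins for a protein–ligand dissociation surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Atom, SegmentMap, Topology, Trajectory
from .metadynamics import CollectiveVariableSpec, coordination_number
from .screening import CompoundRecord
from .structure import HBondCriteria
from .units import ANGSTROM_PER_NM

__all__ = [
    "BlockCorrelationSpec",
    "ToyPotentialSpec",
    "generate_correlated_trajectory",
    "generate_hbond_system",
    "generate_compound_table",
    "generate_score_matrix",
    "make_toy_potential",
    "DoubleWell1D",
    "TwoChannel2D",
    "HostGuest",
]

PSD_EIGENVALUE_FLOOR = -1e-10


# ---------------------------------------------------------------------------
# block-correlated trajectories
# ---------------------------------------------------------------------------

@dataclass
class BlockCorrelationSpec:
    """Target correlation structure for a synthetic Cα trajectory.

    Residues inside one segment share ``within_block_rho``; residue pairs
    across two segments share the value ``cross_block_rho`` maps their
    segment pair to (0 where unmapped).  ``noise_sd`` is the per-coordinate
    displacement scale in Å.
    """

    segments: SegmentMap
    n_residues: int
    within_block_rho: float = 0.9
    cross_block_rho: dict[tuple[str, str], float] = field(default_factory=dict)
    n_frames: int = 10_000
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (-1 < self.within_block_rho < 1):
            raise ValueError("within_block_rho must lie in (-1, 1)")
        for pair, rho in self.cross_block_rho.items():
            if not (-1 <= rho <= 1):
                raise ValueError(f"cross_block_rho for {pair} must lie in [-1, 1]")


def _helical_backbone(n_residues: int) -> np.ndarray:
    """Cα positions on an ideal α-helix (rise 1.5 Å, 100°/residue, r 2.3 Å)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _ca_topology(n_residues: int, chain_id: str = "A") -> Topology:
    return Topology(
        [
            Atom(
                atom_id=i + 1, atom_name="CA", element="C", residue_index=i + 1,
                residue_name="ALA", chain_id=chain_id, is_hydrogen=False,
            )
            for i in range(n_residues)
        ]
    )


def _correlation_matrix(spec: BlockCorrelationSpec) -> np.ndarray:
    n = spec.n_residues
    seg_of = np.array([""] * n, dtype=object)
    for seg in spec.segments:
        lo, hi = seg.start - 1, min(seg.end, n)
        seg_of[lo:hi] = seg.name
    corr = np.eye(n)
    cross = {frozenset(k): v for k, v in spec.cross_block_rho.items()}
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = seg_of[i], seg_of[j]
            if si and si == sj:
                corr[i, j] = corr[j, i] = spec.within_block_rho
            elif si and sj:
                corr[i, j] = corr[j, i] = cross.get(frozenset((si, sj)), 0.0)
    return corr


def generate_correlated_trajectory(
    spec: BlockCorrelationSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Synthesize a Cα trajectory with a known cross-correlation matrix.

    Per-residue displacements are drawn from a multivariate normal with the
    block correlation structure, independently for the three Cartesian
    components (isotropic mapping).  The dot-product covariance of the 3-D
    displacements is then exactly 3× the scalar covariance, so the target
    Pearson matrix equals the scalar correlation matrix, which is returned
    as ground truth.  The implied correlation matrix is validated positive
    semi-definite before sampling; a non-PSD request fails loudly rather
    than being silently repaired.
    """
    corr = _correlation_matrix(spec)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < PSD_EIGENVALUE_FLOOR:
        raise ValueError(
            f"requested correlation structure is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3e})"
        )
    rng = np.random.default_rng(spec.seed)
    # eigh-based square root: deterministic and PSD-safe
    w, v = np.linalg.eigh(corr)
    sqrt_corr = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    base = _helical_backbone(spec.n_residues)
    z = rng.standard_normal((3, spec.n_frames, spec.n_residues))
    disp = spec.noise_sd * np.einsum("cfj,ij->cfi", z, sqrt_corr)
    coords = base[None, :, :] + np.moveaxis(disp, 0, -1)
    return Trajectory(_ca_topology(spec.n_residues), coords), corr


# ---------------------------------------------------------------------------
# H-bond systems
# ---------------------------------------------------------------------------

def generate_hbond_system(
    n_frames: int,
    bonded_frame_fraction: float,
    criteria: HBondCriteria = HBondCriteria(),
    seed: int = 0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Donor–H–acceptor system bonded in exactly round(fraction·n) frames.

    The topology is one N–H donor pair and one carbonyl-oxygen acceptor.
    Bonded frames place the acceptor at 2.9 Å from the donor on the N–H
    axis (angle 180°); unbonded frames move it to 8 Å.  Sub-0.05 Å jitter
    keeps frames distinct without crossing the criteria.  Returns the
    trajectory plus a truth table with the designed occupancy.
    """
    if not (0.0 <= bonded_frame_fraction <= 1.0):
        raise ValueError("bonded_frame_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bonded = round(bonded_frame_fraction * n_frames)
    bonded_mask = np.zeros(n_frames, dtype=bool)
    bonded_mask[rng.permutation(n_frames)[:n_bonded]] = True
    top = Topology(
        [
            Atom(1, "N", "N", 1, "ALA", "A", False),
            Atom(2, "H", "H", 1, "ALA", "A", True),
            Atom(3, "O", "O", 2, "GLY", "A", False),
        ]
    )
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1, 0] = 1.0  # H along +x from N
    coords[:, 2, 0] = np.where(bonded_mask, 2.9, 8.0)
    coords += rng.uniform(-0.05, 0.05, size=coords.shape) * 0.5
    truth = pd.DataFrame(
        {
            "donor_atom": [1],
            "hydrogen_atom": [2],
            "acceptor_atom": [3],
            "occupancy": [n_bonded / n_frames if n_frames else 0.0],
        }
    )
    return Trajectory(top, coords), truth


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_RULE_VIOLATION_VALUES = {
    "MW": ("mw", 650.0),
    "HBD": ("hbd", 7),
    "HBA": ("hba", 13),
    "LOGP": ("logp", 6.5),
    "ROTATABLE": ("rotatable_bonds", 14),
}


def generate_compound_table(
    n: int,
    pass_fraction_per_rule: dict[str, float] | float = 1.0,
    seed: int = 0,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Compound descriptors with exactly determined filter outcomes.

    For each rule (MW, HBD, HBA, LOGP, ROTATABLE) a fraction of compounds is
    made to violate exactly that rule and no other, so the filter's
    rejection tally is known in advance.  Violating sets are disjoint; the
    requested violation fractions must therefore sum to ≤ 1.  Returns the
    records and a truth table (compound_id, passes, violated_rule).
    """
    rules = list(_RULE_VIOLATION_VALUES)
    if isinstance(pass_fraction_per_rule, (int, float)):
        fractions = {r: float(pass_fraction_per_rule) for r in rules}
    else:
        fractions = {r: float(pass_fraction_per_rule.get(r, 1.0)) for r in rules}
    for r, fr in fractions.items():
        if not (0.0 <= fr <= 1.0):
            raise ValueError(f"pass fraction for {r} must lie in [0, 1]")
    n_violate = {r: round((1.0 - fractions[r]) * n) for r in rules}
    if sum(n_violate.values()) > n:
        raise ValueError("violation fractions sum to more than the table size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    violated_rule = np.array([""] * n, dtype=object)
    pos = 0
    for r in rules:
        k = n_violate[r]
        violated_rule[order[pos : pos + k]] = r
        pos += k
    records: list[CompoundRecord] = []
    for i in range(n):
        base = {
            "mw": float(rng.uniform(250.0, 450.0)),
            "hbd": int(rng.integers(0, 4)),
            "hba": int(rng.integers(1, 9)),
            "logp": float(rng.uniform(0.5, 4.5)),
            "rotatable_bonds": int(rng.integers(0, 9)),
        }
        rule = violated_rule[i]
        if rule:
            field_name, bad_value = _RULE_VIOLATION_VALUES[rule]
            base[field_name] = bad_value
        records.append(
            CompoundRecord(
                compound_id=f"CPD{i:05d}",
                heavy_atom_count=int(rng.integers(15, 40)),
                **base,
            )
        )
    truth = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "passes": violated_rule == "",
            "violated_rule": violated_rule,
        }
    )
    return records, truth


def generate_score_matrix(
    compound_ids: list[str],
    targets: list[str],
    pose_probability: float = 0.7,
    score_range: tuple[float, float] = (-11.0, -5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Random compounds × targets docking-score matrix with missing poses."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(*score_range, size=(len(compound_ids), len(targets)))
    mask = rng.random(scores.shape) < pose_probability
    return pd.DataFrame(
        np.where(mask, scores, np.nan), index=compound_ids, columns=targets
    )


# ---------------------------------------------------------------------------
# toy potentials
# ---------------------------------------------------------------------------

@dataclass
class ToyPotentialSpec:
    """Desk-scale energy landscape with a closed-form dissociation barrier."""

    kind: str  # "double_well_1d" | "two_channel_2d" | "host_guest"
    barrier_kj: float = 12.0  # double_well_1d and host_guest
    saddle_heights_kj: tuple[float, float] = (10.0, 20.0)  # two_channel_2d
    r_bound: float = 4.0  # host_guest minima, Å
    r_unbound: float = 12.0


class DoubleWell1D:
    """V(x) = h·(x² − 1)²: minima at x = ±1, barrier h at x = 0.

    The coordinate is the CV itself (identity map), exercising the engine
    without the chain rule.
    """

    n_dof = 1
    n_cvs = 1

    def __init__(self, barrier_kj: float):
        self.h = float(barrier_kj)
        self.masses = np.array([1.0])
        self.analytic_barrier_kj = self.h

    def energy(self, x: np.ndarray) -> float:
        return float(self.h * (x[0] ** 2 - 1.0) ** 2)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.array([4.0 * self.h * x[0] * (x[0] ** 2 - 1.0)])

    def cv_values(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def cv_jacobian(self, x: np.ndarray) -> np.ndarray:
        return np.eye(1)


def _bump(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C¹ quartic bump (1 − u²)² on |u| < 1, zero outside; returns (b, db/du)."""
    inside = np.abs(u) < 1.0
    b = np.where(inside, (1.0 - u**2) ** 2, 0.0)
    db = np.where(inside, -4.0 * u * (1.0 - u**2), 0.0)
    return b, db


class TwoChannel2D:
    """Bound and unbound valleys joined by two channels of distinct height.

    V(x, y) = (x² − 1)²·C(y), with the transverse profile

        C(y) = h_ridge − (h_ridge − h₁)·b(y − 1) − (h_ridge − h₂)·b(y + 1)

    and b a C¹ bump of unit support.  The lines x = ±1 are zero-energy
    valleys (the basins); the dividing line x = 0 carries a high central
    ridge and exactly two saddle points, (0, +1) at h₁ and (0, −1) at h₂.
    Every path between the valleys crosses x = 0 paying at least
    min(h₁, h₂), attained at the lower saddle, so the analytic barrier is
    min(h₁, h₂) in closed form.
    """

    n_dof = 2
    n_cvs = 2

    def __init__(self, saddle_heights_kj: tuple[float, float]):
        self.h1, self.h2 = map(float, saddle_heights_kj)
        self.h_ridge = 2.0 * max(self.h1, self.h2) + 5.0
        self.masses = np.array([1.0, 1.0])
        self.analytic_barrier_kj = min(self.h1, self.h2)

    def _c(self, y: float) -> tuple[float, float]:
        b1, db1 = _bump(np.asarray(y - 1.0))
        b2, db2 = _bump(np.asarray(y + 1.0))
        val = self.h_ridge - (self.h_ridge - self.h1) * float(b1) \
            - (self.h_ridge - self.h2) * float(b2)
        dval = -(self.h_ridge - self.h1) * float(db1) - (self.h_ridge - self.h2) * float(db2)
        return val, dval

    def energy(self, x: np.ndarray) -> float:
        c, _ = self._c(x[1])
        return float((x[0] ** 2 - 1.0) ** 2 * c)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        c, dc = self._c(x[1])
        gx = 4.0 * x[0] * (x[0] ** 2 - 1.0) * c
        gy = (x[0] ** 2 - 1.0) ** 2 * dc
        return np.array([gx, gy])

    def cv_values(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def cv_jacobian(self, x: np.ndarray) -> np.ndarray:
        return np.eye(2)


class HostGuest:
    """Two particles with a radial double well: bound and unbound distances.

    The six Cartesian coordinates are the degrees of freedom; CV1 is the
    pair coordination number and CV2 the COM distance in nm, both computed
    from coordinates so the bias force exercises the CV chain rule.  The
    host particle is tethered to the origin by a stiff harmonic spring.
    """

    n_dof = 6
    n_cvs = 2

    def __init__(self, spec: ToyPotentialSpec, r0_switch: float = 6.0):
        self.h = float(spec.barrier_kj)
        self.r_bound = float(spec.r_bound)
        self.r_unbound = float(spec.r_unbound)
        self.mid = 0.5 * (self.r_bound + self.r_unbound)
        self.halfwidth = 0.5 * (self.r_unbound - self.r_bound)
        self.k_tether = 100.0  # kJ/mol/Å²
        self.masses = np.array([12.0] * 6)
        self.analytic_barrier_kj = self.h
        self.cv_spec = CollectiveVariableSpec(
            kind="coordination_number", group_a=(0,), group_b=(1,), r0=r0_switch
        )

    def _split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x[:3], x[3:]

    def _pair(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        a, b = self._split(x)
        d = b - a
        return d, float(np.linalg.norm(d))

    def energy(self, x: np.ndarray) -> float:
        a, _ = self._split(x)
        _, r = self._pair(x)
        u = (r - self.mid) / self.halfwidth
        return float(self.h * (u**2 - 1.0) ** 2 + self.k_tether * np.dot(a, a))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        a, _ = self._split(x)
        d, r = self._pair(x)
        u = (r - self.mid) / self.halfwidth
        dvdr = 4.0 * self.h * u * (u**2 - 1.0) / self.halfwidth
        unit = d / r if r > 0 else np.zeros(3)
        g = np.zeros(6)
        g[:3] = -dvdr * unit + 2.0 * self.k_tether * a
        g[3:] = dvdr * unit
        return g

    def cv_values(self, x: np.ndarray) -> np.ndarray:
        frame = np.vstack(self._split(x))
        cn = coordination_number(frame, self.cv_spec)
        _, r = self._pair(x)
        return np.array([cn, r / ANGSTROM_PER_NM])

    def cv_jacobian(self, x: np.ndarray) -> np.ndarray:
        d, r = self._pair(x)
        unit = d / r if r > 0 else np.zeros(3)
        # ds/dr of the rational switch, with the removable point at r = r0
        r0, n, m = self.cv_spec.r0, self.cv_spec.n, self.cv_spec.m
        t = r / r0
        den = 1.0 - t**m
        if abs(den) < 1e-12:
            dsdr = n * (n - m) / (2.0 * m * r0)
        else:
            num = 1.0 - t**n
            dsdr = (-n * t ** (n - 1) * den + m * t ** (m - 1) * num) / (r0 * den**2)
        jac = np.zeros((2, 6))
        jac[0, :3] = -dsdr * unit
        jac[0, 3:] = dsdr * unit
        jac[1, :3] = -unit / ANGSTROM_PER_NM
        jac[1, 3:] = unit / ANGSTROM_PER_NM
        return jac


def make_toy_potential(spec: ToyPotentialSpec):
    """Instantiate a toy system; ``analytic_barrier_kj`` rides on the object."""
    if spec.kind == "double_well_1d":
        return DoubleWell1D(spec.barrier_kj)
    if spec.kind == "two_channel_2d":
        return TwoChannel2D(spec.saddle_heights_kj)
    if spec.kind == "host_guest":
        return HostGuest(spec)
    raise ValueError(f"unknown toy potential kind {spec.kind!r}")
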