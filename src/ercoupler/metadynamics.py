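"""Standard (fixed-height) metadynamics over one or two collective variables.

The engine mirrors the dissociation protocol used for ligand unbinding from
the ERα ligand-binding cavity: CV1 is a contact coordination number between
two atom groups (a smooth count of H-bond or hydrophobic contacts) and CV2
the centre-of-mass separation in nm, with repulsive Gaussian hills of fixed
height (0.6 kJ/mol in the reference protocol) deposited at a fixed pace and
a one-sided harmonic wall restraining CV2.  The free-energy surface is the
negated accumulated bias, and the dissociation barrier ΔG_d# is read off the
surface as the lowest saddle separating the bound and unbound basins, with
replica-to-replica standard deviation as the uncertainty.

Protein-scale dynamics is out of scope; the dynamical substrate here is a
Langevin (BAOAB) integrator on toy potentials — either potentials defined
directly in CV space, or a small host–guest particle system whose CVs are
computed from coordinates so that the bias force passes through the CV
chain rule.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .units import ANGSTROM_PER_NM, kj_to_kcal, kt_kj

__all__ = [
    "CollectiveVariableSpec",
    "GaussianHill",
    "HarmonicWall",
    "MetadynamicsConfig",
    "MetadynamicsState",
    "MetadynamicsRun",
    "FreeEnergySurface",
    "BarrierEstimate",
    "ToyPotential",
    "coordination_number",
    "com_distance",
    "deposit_hill",
    "bias_potential",
    "harmonic_wall_energy",
    "run_langevin_mtd",
    "reconstruct_fes",
    "estimate_barrier",
    "aggregate_replicas",
    "write_hills",
    "read_hills",
]


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollectiveVariableSpec:
    """Definition of one CV: contact coordination number or COM distance.

    ``group_a``/``group_b`` are 0-based coordinate-row indices of the two
    atom groups.  The rational switching function for the coordination
    number uses exponents m > n > 0 and a contact radius r0 in Å.
    """

    kind: str  # "coordination_number" | "com_distance"
    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    r0: float = 3.0
    n: int = 6
    m: int = 12

    def __post_init__(self):
        if self.kind not in ("coordination_number", "com_distance"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if not self.group_a or not self.group_b:
            raise ValueError("CV atom groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("CV atom groups must be disjoint")
        if self.kind == "coordination_number":
            if self.r0 <= 0:
                raise ValueError("switching radius r0 must be positive")
            if not (self.m > self.n > 0):
                raise ValueError("switching exponents must satisfy m > n > 0")


def _switch(r: np.ndarray, r0: float, n: int, m: int) -> np.ndarray:
    """Rational switching s(r) = (1 − (r/r0)^n) / (1 − (r/r0)^m).

    The removable singularity at r = r0 evaluates to the limit n/m.
    """
    t = np.asarray(r, dtype=float) / r0
    num = 1.0 - t**n
    den = 1.0 - t**m
    near = np.abs(den) < 1e-12
    safe_den = np.where(near, 1.0, den)
    s = np.where(near, n / m, num / safe_den)
    return s


def coordination_number(frame: np.ndarray, spec: CollectiveVariableSpec) -> float:
    """Smooth contact count between the two groups of a coordination CV."""
    if spec.kind != "coordination_number":
        raise ValueError("spec is not a coordination-number CV")
    xa = frame[list(spec.group_a)]
    xb = frame[list(spec.group_b)]
    r = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return float(_switch(r, spec.r0, spec.n, spec.m).sum())


def com_distance(
    frame: np.ndarray, masses: np.ndarray, spec: CollectiveVariableSpec
) -> float:
    """Distance between the two groups' centres of mass, in nm (input Å)."""
    if spec.kind != "com_distance":
        raise ValueError("spec is not a COM-distance CV")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    ia, ib = list(spec.group_a), list(spec.group_b)
    ma, mb = masses[ia], masses[ib]
    if ma.sum() == 0 or mb.sum() == 0:
        raise ValueError("zero total mass in a CV group")
    coma = (frame[ia] * ma[:, None]).sum(axis=0) / ma.sum()
    comb = (frame[ib] * mb[:, None]).sum(axis=0) / mb.sum()
    return float(np.linalg.norm(coma - comb)) / ANGSTROM_PER_NM


# ---------------------------------------------------------------------------
# hills, wall, state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianHill:
    """One deposited repulsive Gaussian: centre and width per CV, height kJ/mol."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    deposit_step: int

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if len(self.center) != len(self.widths):
            raise ValueError("center and widths must have the same dimensionality")


@dataclass(frozen=True)
class HarmonicWall:
    """One-sided upper wall on one CV: κ(s − s0)² for s > s0, zero below."""

    cv_index: int
    position: float
    force_constant: float = 1000.0  # kJ/mol per CV-unit²


@dataclass
class MetadynamicsConfig:
    """Run parameters for a standard-metadynamics simulation.

    ``pace`` is in integrator steps; with ``dt_ps`` it fixes the deposition
    interval in time (the reference protocol deposits every 4 ps).
    """

    hill_height: float = 0.6  # kJ/mol
    hill_widths: tuple[float, ...] = (0.1,)
    pace: int = 500
    temperature: float = 310.0  # K
    total_steps: int = 100_000
    seed: int = 0
    dt_ps: float = 0.004
    friction: float = 5.0  # 1/ps
    wall: HarmonicWall | None = None

    def __post_init__(self):
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.hill_height <= 0:
            raise ValueError("hill height must be positive")

    def to_dict(self) -> dict:
        d = {
            "hill_height": self.hill_height,
            "hill_widths": list(self.hill_widths),
            "pace": self.pace,
            "temperature": self.temperature,
            "total_steps": self.total_steps,
            "seed": self.seed,
            "dt_ps": self.dt_ps,
            "friction": self.friction,
        }
        if self.wall is not None:
            d["wall"] = {
                "cv_index": self.wall.cv_index,
                "position": self.wall.position,
                "force_constant": self.wall.force_constant,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetadynamicsConfig":
        d = dict(d)
        wall = d.pop("wall", None)
        cfg = cls(**{**d, "hill_widths": tuple(d.get("hill_widths", (0.1,)))})
        if wall is not None:
            cfg.wall = HarmonicWall(**wall)
        return cfg


class MetadynamicsState:
    """Accumulated hill list with vectorised bias evaluation."""

    def __init__(self, n_cvs: int):
        self.n_cvs = n_cvs
        self.hills: list[GaussianHill] = []
        self._centers = np.empty((0, n_cvs))
        self._inv_two_sigma2 = np.empty((0, n_cvs))
        self._heights = np.empty((0,))

    def add(self, hill: GaussianHill) -> None:
        if len(hill.center) != self.n_cvs:
            raise ValueError("hill dimensionality does not match state")
        self.hills.append(hill)
        self._centers = np.vstack([self._centers, np.asarray(hill.center)])
        self._inv_two_sigma2 = np.vstack(
            [self._inv_two_sigma2, 1.0 / (2.0 * np.asarray(hill.widths) ** 2)]
        )
        self._heights = np.append(self._heights, hill.height)

    def bias(self, s: np.ndarray) -> np.ndarray:
        """Bias V(s) at CV points of shape (..., n_cvs), in kJ/mol."""
        s = np.asarray(s, dtype=float)
        if self._heights.size == 0:
            return np.zeros(s.shape[:-1])
        d2 = ((s[..., None, :] - self._centers) ** 2 * self._inv_two_sigma2).sum(axis=-1)
        return (self._heights * np.exp(-d2)).sum(axis=-1)

    def bias_gradient(self, s: np.ndarray) -> np.ndarray:
        """∂V/∂s at one CV point of shape (n_cvs,)."""
        s = np.asarray(s, dtype=float)
        if self._heights.size == 0:
            return np.zeros(self.n_cvs)
        diff = s - self._centers  # (H, n_cvs)
        d2 = (diff**2 * self._inv_two_sigma2).sum(axis=1)
        g = self._heights * np.exp(-d2)  # (H,)
        return (-2.0 * self._inv_two_sigma2 * diff * g[:, None]).sum(axis=0)


def deposit_hill(
    state: MetadynamicsState,
    cv_values: Sequence[float],
    config: MetadynamicsConfig,
    step: int = 0,
) -> MetadynamicsState:
    """Append one Gaussian hill at the current CV values (mutates state)."""
    state.add(
        GaussianHill(
            center=tuple(float(v) for v in cv_values),
            widths=tuple(config.hill_widths),
            height=config.hill_height,
            deposit_step=step,
        )
    )
    return state


def bias_potential(hills: Sequence[GaussianHill], points: np.ndarray) -> np.ndarray:
    """Total bias of a hill list at CV points of shape (..., n_cvs)."""
    hills = list(hills)
    if not hills:
        return np.zeros(np.asarray(points).shape[:-1])
    state = MetadynamicsState(len(hills[0].center))
    for h in hills:
        state.add(h)
    return state.bias(points)


def harmonic_wall_energy(cv_value: float, wall: HarmonicWall) -> tuple[float, float]:
    """Energy and gradient of a one-sided upper wall at one CV value."""
    delta = cv_value - wall.position
    if delta <= 0:
        return 0.0, 0.0
    return wall.force_constant * delta**2, 2.0 * wall.force_constant * delta


# ---------------------------------------------------------------------------
# toy dynamics substrate
# ---------------------------------------------------------------------------

class ToyPotential(Protocol):
    """Differentiable system the Langevin engine can integrate.

    ``n_dof`` coordinates x with per-dof masses; CVs are a differentiable
    map of x with Jacobian.  Direct-CV potentials use the identity map.
    """

    n_dof: int
    n_cvs: int
    masses: np.ndarray

    def energy(self, x: np.ndarray) -> float: ...
    def gradient(self, x: np.ndarray) -> np.ndarray: ...
    def cv_values(self, x: np.ndarray) -> np.ndarray: ...
    def cv_jacobian(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class MetadynamicsRun:
    """Output of one metadynamics run: hills, sampled CVs, final state."""

    config: MetadynamicsConfig
    hills: list[GaussianHill]
    cv_trajectory: np.ndarray  # (n_samples, n_cvs)
    sample_stride: int
    state: MetadynamicsState


def run_langevin_mtd(
    system: ToyPotential,
    config: MetadynamicsConfig,
    x0: np.ndarray,
    sample_stride: int = 100,
    bias_enabled: bool = True,
) -> MetadynamicsRun:
    """Integrate Langevin (BAOAB) dynamics with metadynamics biasing.

    Forces are −∇(V_system + V_bias + V_wall), the bias force passing
    through the CV Jacobian.  Hills are deposited every ``pace`` steps at
    the instantaneous CV values.  The run is reproducible: the hill list is
    a deterministic function of the configuration and seed.
    """
    rng = np.random.default_rng(config.seed)
    kt = kt_kj(config.temperature)
    dt = config.dt_ps
    masses = np.asarray(system.masses, dtype=float)
    x = np.array(x0, dtype=float)
    if x.shape != (system.n_dof,):
        raise ValueError(f"x0 must have shape ({system.n_dof},)")
    v = rng.normal(0.0, np.sqrt(kt / masses))
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * kt / masses)
    state = MetadynamicsState(system.n_cvs)

    def force(x: np.ndarray) -> np.ndarray:
        f = -system.gradient(x)
        s = system.cv_values(x)
        jac = system.cv_jacobian(x)
        grad_s = np.zeros(system.n_cvs)
        if bias_enabled:
            grad_s += state.bias_gradient(s)
        if config.wall is not None:
            _, dw = harmonic_wall_energy(float(s[config.wall.cv_index]), config.wall)
            grad_s[config.wall.cv_index] += dw
        return f - jac.T @ grad_s

    f = force(x)
    samples = []
    for step in range(1, config.total_steps + 1):
        # BAOAB: half kick, half drift, thermostat, half drift, half kick
        v = v + 0.5 * dt * f / masses
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=system.n_dof)
        x = x + 0.5 * dt * v
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"integration diverged at step {step}")
        if bias_enabled and step % config.pace == 0:
            deposit_hill(state, system.cv_values(x), config, step)
        f = force(x)
        v = v + 0.5 * dt * f / masses
        if step % sample_stride == 0:
            samples.append(system.cv_values(x))
    return MetadynamicsRun(
        config=config,
        hills=list(state.hills),
        cv_trajectory=np.array(samples) if samples else np.empty((0, system.n_cvs)),
        sample_stride=sample_stride,
        state=state,
    )


# ---------------------------------------------------------------------------
# FES reconstruction and barrier extraction
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Free energy on a regular CV grid, in kJ/mol, minimum shifted to 0."""

    axes: tuple[np.ndarray, ...]  # one 1-D coordinate array per CV
    values: np.ndarray  # shape = tuple(len(ax) for ax in axes)

    def __post_init__(self):
        if self.values.shape != tuple(len(ax) for ax in self.axes):
            raise ValueError("FES values shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FES must be finite everywhere")

    @property
    def n_cvs(self) -> int:
        return len(self.axes)

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {f"cv{i + 1}": m.ravel() for i, m in enumerate(mesh)}
        data["free_energy_kj"] = self.values.ravel()
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FreeEnergySurface":
        df = pd.read_csv(path, sep="\t")
        cv_cols = [c for c in df.columns if c.startswith("cv")]
        axes = tuple(np.unique(df[c].to_numpy()) for c in cv_cols)
        shape = tuple(len(a) for a in axes)
        return cls(axes, df["free_energy_kj"].to_numpy().reshape(shape))


def reconstruct_fes(
    hills: Sequence[GaussianHill],
    grid_spec: Sequence[tuple[float, float, int]],
) -> FreeEnergySurface:
    """Standard-metadynamics estimator: F(s) = −V_bias(s), shifted to min 0.

    ``grid_spec`` gives (lo, hi, n_points) per CV.
    """
    hills = list(hills)
    if not hills:
        raise ValueError("cannot reconstruct an FES from an empty hill list")
    axes = tuple(np.linspace(lo, hi, n) for lo, hi, n in grid_spec)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    fes = -bias_potential(hills, mesh)
    fes -= fes.min()
    return FreeEnergySurface(axes, fes)


@dataclass
class BarrierEstimate:
    """Replica barriers with mean and sample standard deviation, kcal/mol."""

    per_replica_barriers: tuple[float, ...]
    mean: float
    sd: float  # NaN for a single replica

    def __str__(self) -> str:
        sd = "undefined" if np.isnan(self.sd) else f"{self.sd:.2f}"
        return f"{self.mean:.2f} ± {sd} kcal/mol (n={len(self.per_replica_barriers)})"


def _region_mask(fes: FreeEnergySurface, region: Sequence[tuple[float, float]]) -> np.ndarray:
    if len(region) != fes.n_cvs:
        raise ValueError("region must give (lo, hi) per CV")
    mask = np.ones(fes.values.shape, dtype=bool)
    for dim, (lo, hi) in enumerate(region):
        ax = fes.axes[dim]
        in_ax = (ax >= lo) & (ax <= hi)
        shape = [1] * fes.n_cvs
        shape[dim] = len(ax)
        mask &= in_ax.reshape(shape)
    return mask


def estimate_barrier(
    fes: FreeEnergySurface,
    bound_region: Sequence[tuple[float, float]],
    unbound_region: Sequence[tuple[float, float]],
) -> float:
    """Dissociation barrier between two basins, in kcal/mol.

    The barrier is the minimax saddle: over all grid paths from the bound
    basin's minimum to the unbound basin's minimum, the smallest achievable
    maximum free energy, minus the bound minimum.  Found by a Dijkstra-style
    widest-bottleneck search over orthogonal grid neighbours, which makes
    "inspecting the 2-D FES map" algorithmic and channel-aware: with two
    escape channels the lower saddle wins.
    """
    bmask = _region_mask(fes, bound_region)
    umask = _region_mask(fes, unbound_region)
    if not bmask.any() or not umask.any():
        raise ValueError("bound/unbound regions contain no grid points")
    if (bmask & umask).any():
        raise ValueError("bound and unbound regions overlap")
    vals = fes.values
    start = np.unravel_index(np.where(bmask, vals, np.inf).argmin(), vals.shape)
    bound_min = float(vals[start])
    # minimax path search: priority = max FES along path so far
    best = np.full(vals.shape, np.inf)
    best[start] = vals[start]
    heap = [(float(vals[start]), start)]
    shape = vals.shape
    ndim = vals.ndim
    while heap:
        ceil, node = heapq.heappop(heap)
        if ceil > best[node]:
            continue
        if umask[node]:
            return kj_to_kcal(ceil - bound_min)
        for dim in range(ndim):
            for step in (-1, 1):
                nb = list(node)
                nb[dim] += step
                if not (0 <= nb[dim] < shape[dim]):
                    continue
                nb = tuple(nb)
                new_ceil = max(ceil, float(vals[nb]))
                if new_ceil < best[nb]:
                    best[nb] = new_ceil
                    heapq.heappush(heap, (new_ceil, nb))
    raise ValueError("unbound region not reachable on the grid")


def aggregate_replicas(barriers: Sequence[float]) -> BarrierEstimate:
    """Mean and sample standard deviation over replica barriers (kcal/mol).

    The uncertainty convention follows the replica protocol: three
    independent runs, sd over their barriers.  A single replica has an
    undefined sd, reported as NaN.
    """
    b = [float(x) for x in barriers]
    if not b:
        raise ValueError("need at least one replica barrier")
    mean = float(np.mean(b))
    sd = float(np.std(b, ddof=1)) if len(b) >= 2 else float("nan")
    if len(b) >= 2:
        assert min(b) <= mean <= max(b)
    return BarrierEstimate(tuple(b), mean, sd)


# ---------------------------------------------------------------------------
# HILLS text interchange (PLUMED dialect)
# ---------------------------------------------------------------------------

def write_hills(hills: Sequence[GaussianHill], path: str | Path, dt_ps: float = 1.0) -> None:
    """Write a hill list in the PLUMED HILLS text dialect."""
    hills = list(hills)
    n_cvs = len(hills[0].center) if hills else 1
    cv_names = [f"cv{i + 1}" for i in range(n_cvs)]
    fields = ["time"] + cv_names + [f"sigma_{c}" for c in cv_names] + ["height"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for h in hills:
            row = [h.deposit_step * dt_ps, *h.center, *h.widths, h.height]
            fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def read_hills(path: str | Path, dt_ps: float = 1.0) -> list[GaussianHill]:
    """Read a PLUMED-dialect HILLS file back into GaussianHill records."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ValueError("HILLS file must start with a '#! FIELDS' header")
        fields = header.split()[2:]
        n_cvs = sum(1 for f in fields if f.startswith("cv") and not f.startswith("sigma"))
        hills = []
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            vals = [float(v) for v in line.split()]
            t, centers, widths, height = (
                vals[0], vals[1 : 1 + n_cvs], vals[1 + n_cvs : 1 + 2 * n_cvs], vals[1 + 2 * n_cvs]
            )
            hills.append(
                GaussianHill(tuple(centers), tuple(widths), height, int(round(t / dt_ps)))
            )
    return hills
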