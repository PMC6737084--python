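"""Dynamic cross-correlation maps and inter-segment coupling scores.

The covariance between two atoms is the time average of the dot product of
their mean-free position vectors,

    C_ij = ⟨(r_i − ⟨r_i⟩) · (r_j − ⟨r_j⟩)⟩   [Å²],

computed after a least-squares superposition of every frame onto the first,
which removes rigid-body rotation and translation.  Normalizing by the two
standard deviations gives the Pearson cross-correlation CC_ij ∈ [−1, +1]:
+1 is lockstep motion, −1 fully anti-correlated motion.

The segment (helix) coupling score compresses the per-residue map: CC values
with |CC| below a noise threshold (0.6 by default) are discarded, the
surviving values between two segments are summed, and the sum is divided by
the product of the numbers of residues contributing on either side — a
"correlation density" that makes scores comparable between helices of
different length.

By convention the map is computed over one Cα atom per residue; the atom
selection is an argument, so an all-heavy-atom map is a one-liner if wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import AtomSelection, SegmentMap, Topology, Trajectory

__all__ = [
    "CovarianceMatrix",
    "CrossCorrelationMatrix",
    "SegmentCorrelationTable",
    "rms_fit_trajectory",
    "covariance_matrix",
    "cross_correlation_matrix",
    "segment_correlation_score",
    "per_residue_profile",
    "covariance_spectrum",
]

log = logging.getLogger(__name__)

DEFAULT_NOISE_THRESHOLD = 0.6


@dataclass
class CovarianceMatrix:
    """Symmetric per-atom positional covariance matrix in Å²."""

    values: np.ndarray
    atom_ids: tuple[int, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.atom_ids):
            raise ValueError("covariance matrix must be square over atom_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric to 1e-10")
        if np.any(np.diag(v) < -1e-12):
            raise ValueError("covariance diagonal must be non-negative")
        self.values = v


@dataclass
class CrossCorrelationMatrix:
    """Symmetric Pearson cross-correlation matrix, entries in [−1, 1].

    ``zero_variance_atom_ids`` flags atoms whose positional variance vanished;
    their off-diagonal correlations are set to 0 rather than NaN.
    """

    values: np.ndarray
    atom_ids: tuple[int, ...]
    zero_variance_atom_ids: tuple[int, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("cross-correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("cross-correlation entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.atom_ids, columns=self.atom_ids)


@dataclass
class SegmentCorrelationTable:
    """Noise-filtered, density-normalized coupling scores between segments."""

    entries: pd.DataFrame  # columns: segment_i, segment_j, score, n_contributing_pairs
    threshold_used: float

    def score(self, segment_i: str, segment_j: str) -> float:
        e = self.entries
        m = ((e.segment_i == segment_i) & (e.segment_j == segment_j)) | (
            (e.segment_i == segment_j) & (e.segment_j == segment_i)
        )
        rows = e[m]
        if rows.empty:
            raise KeyError(f"no entry for segment pair ({segment_i}, {segment_j})")
        return float(rows.iloc[0]["score"])


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch_transform(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid rotation/translation mapping ``mobile`` onto ``reference``.

    Returns (rotation matrix, mobile centroid, reference centroid); apply as
    ``(x - mobile_centroid) @ R.T + reference_centroid``.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def rms_fit_trajectory(
    traj: Trajectory,
    fit_selection: AtomSelection,
    reference: str = "first_frame",
) -> Trajectory:
    """Least-squares superpose every frame onto frame 0 over a selection.

    The optimal rotation and translation are found on the fit selection and
    applied to all atoms, removing the rigid-body component of the motion.
    A degenerate reference (fewer than 3 atoms, or collinear) is rejected
    because the rotation is then underdetermined.
    """
    if reference != "first_frame":
        raise ValueError(f"unsupported reference {reference!r}")
    idx = fit_selection.indices()
    if idx.size < 3:
        raise ValueError("RMS fit needs at least 3 atoms in the fit selection")
    ref = traj.coordinates[0, idx]
    # collinearity check: rank of centered reference must be >= 2
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("fit selection is collinear in the reference frame")
    out = np.empty_like(traj.coordinates)
    out[0] = traj.coordinates[0]
    for f in range(1, traj.n_frames):
        rot, mc, rc = _kabsch_transform(traj.coordinates[f, idx], ref)
        out[f] = (traj.coordinates[f] - mc) @ rot.T + rc
    return Trajectory(traj.topology, out, traj.frame_times_ps)


# ---------------------------------------------------------------------------
# covariance / cross-correlation
# ---------------------------------------------------------------------------

def covariance_matrix(
    traj: Trajectory,
    selection: AtomSelection,
    window: tuple[int, int] | None = None,
) -> CovarianceMatrix:
    """Positional covariance C_ij over a frame window (end-exclusive).

    The trajectory is expected to be RMS-fit already; this function does not
    re-superpose.  C_ij is the average over frames of the dot product of the
    two atoms' displacement vectors from their time means.
    """
    idx = selection.indices()
    if idx.size == 0:
        raise ValueError("empty selection")
    lo, hi = (0, traj.n_frames) if window is None else window
    x = traj.coordinates[lo:hi, idx, :]  # (F, n, 3)
    if x.shape[0] < 2:
        raise ValueError(f"covariance window has {x.shape[0]} frames; need at least 2")
    x = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fid,fjd->ij", x, x) / x.shape[0]
    cov = 0.5 * (cov + cov.T)  # kill float asymmetry
    return CovarianceMatrix(cov, tuple(int(i) for i in idx + 1))


def cross_correlation_matrix(cov: CovarianceMatrix) -> CrossCorrelationMatrix:
    """Normalize a covariance matrix to Pearson coefficients.

    CC_ij = C_ij / √(C_ii · C_jj).  Atoms with zero variance cannot be
    normalized; their off-diagonal entries are set to 0 and the atoms are
    flagged on the result instead of propagating NaNs.
    """
    var = np.diag(cov.values).copy()
    zero = var <= 0.0
    if np.any(zero):
        flagged = tuple(int(cov.atom_ids[i]) for i in np.nonzero(zero)[0])
        log.warning("zero-variance atoms excluded from normalization: %s", flagged)
    else:
        flagged = ()
    safe_var = np.where(zero, 1.0, var)
    denom = np.sqrt(np.outer(safe_var, safe_var))
    cc = cov.values / denom
    cc[zero, :] = 0.0
    cc[:, zero] = 0.0
    np.fill_diagonal(cc, np.where(zero, 0.0, 1.0))
    cc = np.clip(0.5 * (cc + cc.T), -1.0, 1.0)
    return CrossCorrelationMatrix(cc, cov.atom_ids, flagged)


# ---------------------------------------------------------------------------
# segment scores
# ---------------------------------------------------------------------------

def _residues_of(topology: Topology, atom_ids: tuple[int, ...]) -> np.ndarray:
    """(chain, residue_index) key per matrix row, encoded as structured pairs."""
    idx = np.asarray(atom_ids, dtype=int) - 1
    chains = topology.column("chain_id")[idx]
    resis = topology.column("residue_index")[idx]
    return np.array(list(zip(chains, resis)), dtype=object)


def _segment_rows(
    topology: Topology, segments: SegmentMap, name: str, atom_ids: tuple[int, ...]
) -> np.ndarray:
    """Matrix row indices whose atoms fall in the named segment."""
    idx = np.asarray(atom_ids, dtype=int) - 1
    chains = topology.column("chain_id")[idx]
    resis = topology.column("residue_index")[idx]
    mask = np.zeros(idx.size, dtype=bool)
    for seg in segments.get(name):
        mask |= (chains == seg.chain_id) & (resis >= seg.start) & (resis <= seg.end)
    return np.nonzero(mask)[0]


def segment_correlation_score(
    cc: CrossCorrelationMatrix,
    topology: Topology,
    segments: SegmentMap,
    threshold: float = DEFAULT_NOISE_THRESHOLD,
    density_normalizer: str = "contributing",
) -> SegmentCorrelationTable:
    """Coupling score between every segment pair.

    For a pair (I, J): keep residue-pair correlations with |CC| ≥ threshold
    (values inside the open noise band are discarded), sum them, and divide
    by (number of contributing residues in I) × (number in J).  With
    ``density_normalizer="all"`` the normalizer is instead the full residue
    count of each segment.  A pair with no surviving correlation scores 0.

    The matrix must hold one representative atom per residue (the Cα
    convention); a segment that resolves to no matrix rows is a
    configuration error.
    """
    if density_normalizer not in ("contributing", "all"):
        raise ValueError("density_normalizer must be 'contributing' or 'all'")
    names = segments.names()
    rows: dict[str, np.ndarray] = {}
    for name in names:
        r = _segment_rows(topology, segments, name, cc.atom_ids)
        if r.size == 0:
            raise ValueError(f"segment {name!r} resolves to no atoms in the matrix")
        rows[name] = r
    records = []
    for a in range(len(names)):
        for b in range(a, len(names)):
            ni, nj = names[a], names[b]
            ri, rj = rows[ni], rows[nj]
            block = cc.values[np.ix_(ri, rj)].copy()
            if ni == nj:
                # exclude self-correlation of a residue with itself
                np.fill_diagonal(block, 0.0)
            keep = np.abs(block) >= threshold
            n_pairs = int(keep.sum())
            if ni == nj:
                n_pairs //= 2  # block counted both triangles
            if n_pairs == 0:
                score = 0.0
            else:
                total = float(block[keep].sum())
                if ni == nj:
                    total /= 2.0
                if density_normalizer == "contributing":
                    n_i = int(keep.any(axis=1).sum())
                    n_j = int(keep.any(axis=0).sum())
                else:
                    n_i, n_j = ri.size, rj.size
                score = total / (n_i * n_j)
            records.append(
                {"segment_i": ni, "segment_j": nj, "score": score,
                 "n_contributing_pairs": n_pairs}
            )
    return SegmentCorrelationTable(pd.DataFrame.from_records(records), threshold)


def per_residue_profile(
    cc: CrossCorrelationMatrix,
    topology: Topology,
    focus_segment: str,
    segments: SegmentMap,
    threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> pd.DataFrame:
    """Per-residue sum of (thresholded) correlation to a focus segment.

    For every residue outside the focus segment (H12, typically), sum the
    CC values to all residues of the focus segment whose magnitude reaches
    the threshold; ``threshold=0`` sums the raw coefficients.  Returns a
    DataFrame indexed by (chain_id, residue_index) with a ``cc_sum`` column.
    """
    focus_rows = _segment_rows(topology, segments, focus_segment, cc.atom_ids)
    if focus_rows.size == 0:
        raise ValueError(f"focus segment {focus_segment!r} resolves to no atoms")
    res_keys = _residues_of(topology, cc.atom_ids)
    focus_set = {tuple(res_keys[r]) for r in focus_rows}
    records = []
    for r in range(len(cc.atom_ids)):
        key = tuple(res_keys[r])
        if key in focus_set:
            continue
        vals = cc.values[r, focus_rows]
        kept = vals[np.abs(vals) >= threshold] if threshold > 0 else vals
        records.append(
            {"chain_id": key[0], "residue_index": int(key[1]),
             "cc_sum": float(kept.sum())}
        )
    return pd.DataFrame.from_records(records).set_index(["chain_id", "residue_index"])


def covariance_spectrum(cov: CovarianceMatrix) -> pd.DataFrame:
    """Eigenvalues of the covariance matrix, sorted descending.

    Reports each eigenvalue (Å²) and its fraction of the total variance —
    how representative the corresponding collective mode is of the overall
    dynamics.  No principal-component projection is derived from this.
    """
    vals = np.linalg.eigvalsh(cov.values)[::-1]
    total = vals.sum()
    frac = vals / total if total > 0 else np.zeros_like(vals)
    return pd.DataFrame({"eigenvalue_A2": vals, "variance_fraction": frac})
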