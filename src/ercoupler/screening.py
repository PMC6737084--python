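"""Virtual-screening funnel: property filters and consensus selection.

The funnel removes compounds with poor predicted absorption (Lipinski's rule
of five, as a hard conjunctive filter) or excessive flexibility (> 10
rotatable bonds), then selects candidates from per-target docking scores
against a panel of receptor conformations under one of two consensus rules:

* structure-based: best score ≤ −8.5 kcal/mol on at least one target;
* ligand-based: a favorable pose on at least two distinct targets, with
  at least one score ≤ −7.5 kcal/mol.

"Favorable interactions" is operationalized as the existence of a docking
pose for that target, i.e. a present (non-missing) score in the matrix.
Docking itself is out of scope: the canonical input is a precomputed
descriptor table and score matrix; descriptor computation from structures
is a thin optional layer users can bolt on with a cheminformatics toolkit.

Ligand efficiency normalizes an externally supplied binding free energy by
the number of non-hydrogen atoms, making affinities of differently sized
ligands comparable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "SelectionReport",
    "LIPINSKI_RULES",
    "property_filter",
    "consensus_select_structure_based",
    "consensus_select_ligand_based",
    "ligand_efficiency",
    "read_compound_table",
    "read_score_matrix",
]

STRUCTURE_BASED_CUTOFF = -8.5  # kcal/mol
LIGAND_BASED_CUTOFF = -7.5  # kcal/mol

#: rule name -> (field, upper bound); applied conjunctively, checked in order
LIPINSKI_RULES: dict[str, tuple[str, float]] = {
    "MW": ("mw", 500.0),
    "HBD": ("hbd", 5),
    "HBA": ("hba", 10),
    "LOGP": ("logp", 5.0),
}


@dataclass(frozen=True)
class CompoundRecord:
    """Descriptors needed by the property filter and efficiency metrics."""

    compound_id: str
    mw: float
    hbd: int
    hba: int
    logp: float
    rotatable_bonds: int
    heavy_atom_count: int

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError(f"{self.compound_id}: molecular weight must be positive")
        for f in ("hbd", "hba", "rotatable_bonds", "heavy_atom_count"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.compound_id}: {f} must be non-negative")


@dataclass
class SelectionReport:
    """Consensus-selection outcome, re-checkable against its predicate."""

    protocol: str  # "structure_based" | "ligand_based"
    cutoff: float
    selected: pd.DataFrame  # compound_id, best_score, best_target, n_targets_with_pose

    @property
    def compound_ids(self) -> list[str]:
        return self.selected["compound_id"].tolist()


@dataclass
class FilterResult:
    passing: list[CompoundRecord]
    rejection_tally: Counter  # first failing rule per rejected compound
    rejected_ids: dict[str, str]  # compound_id -> first failing rule


def property_filter(
    compounds: Sequence[CompoundRecord], max_rotatable: int = 10
) -> FilterResult:
    """Lipinski + rotatable-bond filter.

    Keep iff mw ≤ 500 ∧ hbd ≤ 5 ∧ hba ≤ 10 ∧ logp ≤ 5 ∧ rotatable_bonds ≤
    ``max_rotatable``.  The tally records the first failing rule per
    rejection, so tallies sum to (input − passing).
    """
    passing: list[CompoundRecord] = []
    tally: Counter = Counter()
    rejected: dict[str, str] = {}
    for c in compounds:
        failed = None
        for rule, (field_name, bound) in LIPINSKI_RULES.items():
            if getattr(c, field_name) > bound:
                failed = rule
                break
        if failed is None and c.rotatable_bonds > max_rotatable:
            failed = "ROTATABLE"
        if failed is None:
            passing.append(c)
        else:
            tally[failed] += 1
            rejected[c.compound_id] = failed
    return FilterResult(passing, tally, rejected)


def _consensus(
    scores: pd.DataFrame, cutoff: float, min_targets_with_pose: int, protocol: str,
    strict: bool,
) -> SelectionReport:
    if scores.shape[1] < 1:
        raise ValueError("score matrix must have at least one target column")
    if scores.shape[0] < 1:
        raise ValueError("score matrix is empty")
    records = []
    for cid, row in scores.iterrows():
        present = row.dropna()
        if len(present) < min_targets_with_pose:
            continue
        best = present.min()
        hit = best < cutoff if strict else best <= cutoff
        if not hit:
            continue
        records.append(
            {
                "compound_id": cid,
                "best_score": float(best),
                "best_target": present.idxmin(),
                "n_targets_with_pose": int(len(present)),
            }
        )
    selected = pd.DataFrame.from_records(
        records, columns=["compound_id", "best_score", "best_target", "n_targets_with_pose"]
    )
    report = SelectionReport(protocol, cutoff, selected)
    _revalidate(report, scores, min_targets_with_pose, strict)
    return report


def _revalidate(
    report: SelectionReport, scores: pd.DataFrame, min_targets: int, strict: bool
) -> None:
    """Independent re-check of the selection predicate before the report ships."""
    for cid in report.compound_ids:
        present = scores.loc[cid].dropna()
        best = present.min()
        ok = len(present) >= min_targets and (
            best < report.cutoff if strict else best <= report.cutoff
        )
        if not ok:
            raise AssertionError(f"selection re-validation failed for {cid}")


def consensus_select_structure_based(
    scores: pd.DataFrame, cutoff: float = STRUCTURE_BASED_CUTOFF, strict: bool = False
) -> SelectionReport:
    """Select compounds whose best docking score reaches the cutoff.

    ``scores`` is a compounds × targets matrix (kcal/mol; NaN = no favorable
    pose on that target).  A compound is selected iff it has a pose with
    score ≤ cutoff on at least one target.  ``strict=True`` reads "lower
    than" as a strict inequality.
    """
    return _consensus(scores, cutoff, min_targets_with_pose=1,
                      protocol="structure_based", strict=strict)


def consensus_select_ligand_based(
    scores: pd.DataFrame, cutoff: float = LIGAND_BASED_CUTOFF, strict: bool = False
) -> SelectionReport:
    """Select compounds with poses on ≥ 2 targets, at least one within cutoff."""
    return _consensus(scores, cutoff, min_targets_with_pose=2,
                      protocol="ligand_based", strict=strict)


def ligand_efficiency(delta_g_b: float, heavy_atom_count: int) -> float:
    """Binding free energy per non-hydrogen atom, kcal/mol.

    LE = ΔG_b / N_heavy; with negative ΔG_b more negative LE means a more
    efficient binder for its size.
    """
    if heavy_atom_count < 1:
        raise ValueError("heavy_atom_count must be at least 1")
    return float(delta_g_b) / heavy_atom_count


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_COMPOUND_COLUMNS = ["compound_id", "mw", "hbd", "hba", "logp",
                     "rotatable_bonds", "heavy_atom_count"]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a descriptor TSV; every descriptor column is required per record."""
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(_COMPOUND_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"compound table missing columns: {sorted(missing_cols)}")
    bad = df[df[_COMPOUND_COLUMNS].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(
            "compounds with missing descriptors: "
            + ", ".join(str(x) for x in bad["compound_id"].tolist())
        )
    return [
        CompoundRecord(
            compound_id=str(r.compound_id), mw=float(r.mw), hbd=int(r.hbd),
            hba=int(r.hba), logp=float(r.logp),
            rotatable_bonds=int(r.rotatable_bonds),
            heavy_atom_count=int(r.heavy_atom_count),
        )
        for r in df.itertuples()
    ]


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    """Read a compounds × targets score TSV; empty cells mean no pose."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("target column labels must be unique")
    vals = df.to_numpy(dtype=float)
    if np.any(np.isinf(vals)):
        raise ValueError("docking scores must be finite where present")
    return df
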