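"""Run configuration and stage orchestration.

A run is described by a small YAML/dict document: a seed, an output
directory, and an ordered list of stages.  Each stage calls one library
entry point and writes plain TSV/JSON outputs; a serialized copy of the
configuration, its hash, per-stage wall times and the package version are
recorded in ``manifest.json`` inside the output directory, so a rerun from
that copy is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    read_segment_map, read_topology, read_trajectory, select, write_segment_map,
    write_trajectory,
)
from .correlation import (
    covariance_matrix, cross_correlation_matrix, per_residue_profile,
    rms_fit_trajectory, segment_correlation_score,
)
from .metadynamics import (
    FreeEnergySurface, MetadynamicsConfig, aggregate_replicas, estimate_barrier,
    read_hills, reconstruct_fes, run_langevin_mtd, write_hills,
)
from .screening import (
    consensus_select_ligand_based, consensus_select_structure_based,
    property_filter, read_compound_table, read_score_matrix,
)
from .structure import HBondCriteria, daura_cluster, hbond_occupancy
from .synthetic import (
    BlockCorrelationSpec, ToyPotentialSpec, generate_correlated_trajectory,
    make_toy_potential,
)

__all__ = ["run_pipeline", "config_hash", "load_config"]

log = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration document."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _load_traj(stage: dict, base: Path):
    top = read_topology(base / stage["topology"])
    traj = read_trajectory(
        base / stage["trajectory"], top,
        stage.get("trajectory_format", "xyz_multiframe"),
    )
    return top, traj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth_corr(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    segments = read_segment_map(base / stage["segments"])
    spec = BlockCorrelationSpec(
        segments=segments,
        n_residues=int(stage["n_residues"]),
        within_block_rho=float(stage.get("within_block_rho", 0.9)),
        cross_block_rho={
            tuple(k.split(":")): float(v)
            for k, v in stage.get("cross_block_rho", {}).items()
        },
        n_frames=int(stage.get("n_frames", 10_000)),
        noise_sd=float(stage.get("noise_sd", 0.5)),
        seed=int(stage.get("seed", seed)),
    )
    traj, true_cc = generate_correlated_trajectory(spec)
    # topology file needs a single frame; the full trajectory goes to XYZ
    first = type(traj)(traj.topology, traj.coordinates[:1])
    write_trajectory(first, out / "synthetic_topology.pdb", "pdb_multimodel")
    write_trajectory(traj, out / "synthetic_trajectory.xyz", "xyz_multiframe")
    write_segment_map(segments, out / "segments.tsv")
    _write_tsv(pd.DataFrame(true_cc), out / "true_cc.tsv")
    return ["synthetic_topology.pdb", "synthetic_trajectory.xyz", "segments.tsv", "true_cc.tsv"]


def _stage_corr(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    top, traj = _load_traj(stage, base)
    segments = read_segment_map(base / stage["segments"])
    fit_name = stage.get("fit_selection", "CA")
    sel = select(top, name=fit_name)
    fitted = rms_fit_trajectory(traj, sel) if stage.get("fit", True) else traj
    cov = covariance_matrix(fitted, sel)
    cc = cross_correlation_matrix(cov)
    threshold = float(stage.get("threshold", 0.6))
    table = segment_correlation_score(cc, top, segments, threshold)
    _write_tsv(cc.to_frame(), out / "cc_matrix.tsv", index=True)
    _write_tsv(table.entries, out / "segment_scores.tsv")
    outputs = ["cc_matrix.tsv", "segment_scores.tsv"]
    focus = stage.get("focus_segment")
    if focus:
        prof = per_residue_profile(
            cc, top, focus, segments, float(stage.get("profile_threshold", threshold))
        )
        _write_tsv(prof.reset_index(), out / "per_residue_profile.tsv")
        outputs.append("per_residue_profile.tsv")
    discarded = float(np.mean(np.abs(cc.values) < threshold))
    log.info("corr: %.1f%% of CC entries below the %.2f noise threshold",
             100 * discarded, threshold)
    return outputs


def _stage_cluster(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    top, traj = _load_traj(stage, base)
    sel = select(top, name=stage.get("selection", "CA"))
    res = daura_cluster(traj, sel, float(stage.get("cutoff", 2.0)))
    _write_tsv(res.to_frame(), out / "clusters.tsv")
    return ["clusters.tsv"]


def _stage_hbonds(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    top, traj = _load_traj(stage, base)
    donors = select(top, element=stage.get("donor_element", "N"))
    acceptors = select(top, element=stage.get("acceptor_element", "O"))
    criteria = HBondCriteria(
        float(stage.get("max_da_distance", 3.5)), float(stage.get("min_dha_angle", 120.0))
    )
    table = hbond_occupancy(
        traj, donors, acceptors, criteria, float(stage.get("floor", 0.0))
    )
    _write_tsv(table, out / "hbond_occupancy.tsv")
    return ["hbond_occupancy.tsv"]


def _stage_mtd_run(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    spec = ToyPotentialSpec(**stage.get("potential", {"kind": "double_well_1d"}))
    system = make_toy_potential(spec)
    cfg = MetadynamicsConfig.from_dict(
        {**stage.get("mtd", {}), "seed": int(stage.get("seed", seed))}
    )
    x0 = np.asarray(stage.get("x0", [-1.0] * system.n_dof), dtype=float)
    run = run_langevin_mtd(system, cfg, x0)
    write_hills(run.hills, out / "HILLS", cfg.dt_ps)
    np.savetxt(out / "cv_trajectory.tsv", run.cv_trajectory, delimiter="\t")
    return ["HILLS", "cv_trajectory.tsv"]


def _stage_mtd_fes(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    hills = read_hills(base / stage["hills"], float(stage.get("dt_ps", 1.0)))
    grid = [tuple(g) for g in stage["grid"]]  # [[lo, hi, n], ...]
    fes = reconstruct_fes(hills, grid)
    fes.write_tsv(out / "fes.tsv")
    return ["fes.tsv"]


def _stage_mtd_barrier(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    fes = FreeEnergySurface.read_tsv(base / stage["fes"])
    barrier = estimate_barrier(
        fes, [tuple(r) for r in stage["bound"]], [tuple(r) for r in stage["unbound"]]
    )
    (out / "barrier.json").write_text(json.dumps({"barrier_kcal": barrier}, indent=2))
    return ["barrier.json"]


def _stage_mtd_replicas(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    est = aggregate_replicas([float(b) for b in stage["barriers"]])
    (out / "replica_summary.json").write_text(
        json.dumps(
            {"per_replica_kcal": list(est.per_replica_barriers),
             "mean_kcal": est.mean,
             "sd_kcal": None if np.isnan(est.sd) else est.sd},
            indent=2,
        )
    )
    return ["replica_summary.json"]


def _stage_screen_filter(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    compounds = read_compound_table(base / stage["compounds"])
    res = property_filter(compounds, int(stage.get("max_rotatable", 10)))
    _write_tsv(
        pd.DataFrame({"compound_id": [c.compound_id for c in res.passing]}),
        out / "passing_compounds.tsv",
    )
    (out / "rejection_tally.json").write_text(json.dumps(dict(res.rejection_tally), indent=2))
    return ["passing_compounds.tsv", "rejection_tally.json"]


def _stage_screen_consensus(stage: dict, base: Path, out: Path, seed: int) -> list[str]:
    scores = read_score_matrix(base / stage["scores"])
    protocol = stage.get("protocol", "structure")
    if protocol == "structure":
        report = consensus_select_structure_based(
            scores, float(stage.get("cutoff", -8.5))
        )
    elif protocol == "ligand":
        report = consensus_select_ligand_based(scores, float(stage.get("cutoff", -7.5)))
    else:
        raise ValueError(f"unknown consensus protocol {protocol!r}")
    _write_tsv(report.selected, out / f"selected_{report.protocol}.tsv")
    return [f"selected_{report.protocol}.tsv"]


def _predicted_outputs(stage: dict) -> list[str]:
    """File names a stage is known to produce, for input pre-checking."""
    kind = stage.get("kind")
    fixed = {
        "synth_corr": ["synthetic_topology.pdb", "synthetic_trajectory.xyz",
                       "segments.tsv", "true_cc.tsv"],
        "corr": ["cc_matrix.tsv", "segment_scores.tsv", "per_residue_profile.tsv"],
        "cluster": ["clusters.tsv"],
        "hbonds": ["hbond_occupancy.tsv"],
        "mtd_run": ["HILLS", "cv_trajectory.tsv"],
        "mtd_fes": ["fes.tsv"],
        "mtd_barrier": ["barrier.json"],
        "mtd_replicas": ["replica_summary.json"],
        "screen_filter": ["passing_compounds.tsv", "rejection_tally.json"],
        "screen_consensus": ["selected_structure_based.tsv", "selected_ligand_based.tsv"],
    }
    return fixed.get(kind, [])


_STAGES = {
    "synth_corr": _stage_synth_corr,
    "corr": _stage_corr,
    "cluster": _stage_cluster,
    "hbonds": _stage_hbonds,
    "mtd_run": _stage_mtd_run,
    "mtd_fes": _stage_mtd_fes,
    "mtd_barrier": _stage_mtd_barrier,
    "mtd_replicas": _stage_mtd_replicas,
    "screen_filter": _stage_screen_filter,
    "screen_consensus": _stage_screen_consensus,
}


def run_pipeline(config: dict, base_dir: str | Path = ".") -> dict:
    """Execute the configured stages in order; returns the manifest.

    Referenced inputs are checked before any stage runs.  On a stage
    failure the partial outputs are retained next to a ``FAILED`` marker
    and the error is re-raised (the CLI converts it into a nonzero exit).
    Stage outputs may reference earlier stages' files via the output
    directory.
    """
    base = Path(base_dir)
    out = base / config.get("output_dir", "ercoupler_out")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    produced: set[str] = set()
    for stage in stages:
        if stage.get("kind") not in _STAGES:
            raise ValueError(f"unknown stage kind {stage.get('kind')!r}")
        for key in ("topology", "trajectory", "segments", "compounds", "scores",
                    "hills", "fes"):
            if key in stage:
                p = base / stage[key]
                if not (p.exists() or (out / stage[key]).exists()
                        or stage[key] in produced):
                    raise FileNotFoundError(f"stage input does not exist: {p}")
        produced.update(_predicted_outputs(stage))
    chash = config_hash(config)
    (out / "run_config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    manifest = {"config_hash": chash, "version": __version__, "seed": seed, "stages": []}
    for i, stage in enumerate(stages):
        kind = stage["kind"]
        t0 = time.perf_counter()
        try:
            # inputs may live in the run's own output dir (chained stages)
            stage_base = out if any(
                key in stage and (out / stage[key]).exists()
                for key in ("topology", "trajectory", "segments", "compounds",
                            "scores", "hills", "fes")
            ) else base
            outputs = _STAGES[kind](stage, stage_base, out, seed)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {i} ({kind}): {exc}\n")
            log.error("stage %d (%s) failed: %s", i, kind, exc)
            raise
        manifest["stages"].append(
            {"index": i, "kind": kind, "outputs": outputs,
             "wall_time_s": round(time.perf_counter() - t0, 4)}
        )
        log.info("stage %d (%s) done in %.2fs", i, kind, time.perf_counter() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
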