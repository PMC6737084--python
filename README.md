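# ercoupler

Trajectory diagnostics for mutant estrogen-receptor-α (ERα) activation and
antiestrogen behaviour, for computational structural biologists working on
endocrine-resistant breast cancer variants (Y537S, Y537N, D538G) or on any
receptor system with a comparable activation signature.

Point mutations in the loop joining helices 11 and 12 of the ERα
ligand-binding domain lock helix 12 (H12) against the H3/H5 groove, an
agonist-like state that keeps the receptor transcriptionally active without
hormone. Diagnosing whether a candidate antagonist disrupts that state — and
how hard it is to pull the ligand back out of the binding cavity — requires a
specific set of trajectory analyses, which this package implements as a
tested, reusable library:

- **Dynamic cross-correlation maps.** For atoms *i*, *j* with position
  vectors **r**ᵢ, **r**ⱼ, the positional covariance
  C_ij = ⟨(**r**ᵢ − ⟨**r**ᵢ⟩)·(**r**ⱼ − ⟨**r**ⱼ⟩)⟩ is computed after
  least-squares superposition onto the first frame, and normalized to the
  Pearson coefficient CC_ij = C_ij / √(C_ii·C_jj) ∈ [−1, +1].
- **Helix-coupling scores (CS).** Entries with |CC| < 0.6 are discarded as
  noise; the surviving values between two segments are summed and divided by
  the product of contributing residue counts (a "correlation density"),
  giving a per-helix-pair coupling score. A persistent positive H12–H3/H5
  score is the activation signature.
- **Conformational clustering and H-bond persistence.** Greedy RMSD-neighbor
  (GROMOS-style) clustering with a deterministic tie-break, and donor–H···
  acceptor occupancy statistics under an explicit geometric criterion
  (default D···A ≤ 3.5 Å, D–H···A ≥ 120°).
- **Standard metadynamics with the dissociation CVs.** Fixed-height Gaussian
  hills (0.6 kJ/mol) over a contact coordination number
  s(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ) and a centre-of-mass separation in nm,
  with a one-sided harmonic wall; the free-energy surface is F(s) =
  −V_bias(s), the dissociation barrier ΔG_d# the lowest saddle between the
  bound and unbound basins (Dijkstra-style minimax search on the FES grid),
  and the uncertainty the standard deviation over three replicas. The
  dynamical substrate is a Langevin (BAOAB) integrator on toy potentials
  with closed-form barriers.
- **Virtual-screening funnel.** Lipinski + rotatable-bond filters and two
  consensus selection rules over per-target docking scores (best score ≤
  −8.5 kcal/mol on ≥ 1 target; poses on ≥ 2 targets with one ≤ −7.5
  kcal/mol), plus ligand efficiency LE = ΔG_b / N_heavy.
- **Synthetic generators** for every input class — block-correlated Cα
  trajectories, H-bond systems with exact designed occupancy, compound
  tables with exact filter tallies, toy landscapes — each returning its
  ground truth, so the whole pipeline is testable without external data.

## Worked example

`examples/toy_dissociation_metadynamics.py` runs three metadynamics replicas
on a 1-D double well whose barrier is 5 k_BT at 310 K and prints:

```
analytic barrier: 12.89 kJ/mol (3.08 kcal/mol)
replica 1: 750 hills, barrier 13.10 kJ/mol
replica 2: 750 hills, barrier 14.07 kJ/mol
replica 3: 750 hills, barrier 11.64 kJ/mol

replica estimate: 3.09 ± 0.29 kcal/mol (n=3)
in kJ/mol: 12.94 ± 1.22 (truth 12.89)
```

Each replica deposits 0.6 kJ/mol hills until the well is filled several
times over, reconstructs F = −V_bias, and reads the barrier off the surface;
the replica mean lands within sampling noise of the analytic 12.89 kJ/mol
and the sd is the uncertainty that would be quoted on a ΔG_d#.

`examples/helix_coupling.py` shows the correlation side: a synthetic
trajectory built with H3–H12 cross-correlation 0.8 yields

```
estimated H3–H12 block CC: 0.800 (generator truth 0.80)
coupling scores (|CC| >= 0.6, correlation-density normalized):
segment_i segment_j    score  n_contributing_pairs
       H3       H12 0.800457                    36
```

i.e. the estimator recovers the designed coupling and the CS table flags the
H3–H12 pair — the activation signature the analysis exists to detect. The
other examples (`clustering_and_hbonds.py`, `screening_funnel.py`) cover the
remaining capabilities the same way.

A thin CLI mirrors the library for shell use:
`ercoupler info|corr|cluster|hbonds|mtd|screen|run` (see `--help` on each
subcommand; `ercoupler run --config pipeline.yaml` executes a multi-stage
YAML-configured pipeline with a manifest and config hash).

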