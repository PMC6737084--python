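# Methods

This note records the models, conventions and design choices behind each
analysis stage, in enough detail to reproduce or audit any number the
package computes.

## Coordinates, units and indexing

Coordinates are Å throughout; centre-of-mass CV distances are reported in
nm (the convention for that collective variable). Energies carry explicit
units: hill heights and free-energy surfaces are kJ/mol, dissociation
barriers and docking scores kcal/mol, with the single conversion
1 kcal = 4.184 kJ centralized in `ercoupler.units`. Residue indexing is
1-based and inclusive on both ends, matching PDB convention; multi-chain
dimers are supported through `chain_id`, and segment maps may define the
same helix name per chain so analyses can run per monomer. Input
trajectories are assumed whole-molecule imaged — periodic-boundary
unwrapping is upstream MD tooling's job and is not attempted here.

## Cross-correlation maps and coupling scores

The covariance is the scalar (dot-product) covariance of the two atoms'
3-D displacement vectors, C_ij = ⟨Δ**r**ᵢ·Δ**r**ⱼ⟩ — not the 3N×3N
Cartesian covariance, of which only the eigenvalue spectrum is exposed
(`covariance_spectrum`, sorted eigenvalues and variance fractions; no
principal-component projection is built on it). By default the map is
computed over one Cα atom per residue, the standard DCCM convention; the
selection is an argument, so heavier selections are available.

Frames are superposed onto the first frame over the fit selection before
estimation (optimal rigid rotation + translation via least squares). One
caveat the synthetic tests make visible: when the correlated motion of
interest itself resembles a rigid-body mode (small systems, large
correlated blocks), the fit partially absorbs it and attenuates the
estimated CC. Real receptor trajectories have enough uncorrelated bulk to
pin the fit; the generators emit trajectories that are already in a common
frame, so the recovery tests estimate without re-fitting and the fit is
validated separately by its own invariance property (rigidly transforming
every input frame changes no CC entry by more than 1e-8).

Coupling scores discard |CC_ij| < 0.6 as noise. The threshold test is
inclusive (|CC| ≥ 0.6 survives): the noise band is the open interval, so
boundary values contribute; both the threshold and the comparison are
configurable. The normalizer is the product of the numbers of residues
*contributing* at least one surviving pair on each side ("correlation
density"); `density_normalizer="all"` switches to the full segment residue
counts. A pair with no surviving entry scores exactly 0. Zero-variance
atoms cannot be Pearson-normalized; they are flagged on the result and
their off-diagonal entries set to 0 rather than propagating NaNs. The
per-residue profile against a focus segment (typically H12) applies the
same threshold by default; passing `threshold=0` sums raw coefficients,
since either convention is defensible for profile plots.

## Clustering and hydrogen bonds

Pairwise frame RMSDs always use least-squares fitting. Greedy
neighbor clustering repeatedly extracts the frame with the most remaining
neighbors within the cutoff; ties are broken toward the lowest frame index,
making the output deterministic (the original algorithm leaves the
tie-break open). Cluster ids are emitted in extraction order, which is
provably non-increasing size order.

The H-bond criterion defaults to donor–acceptor ≤ 3.5 Å and donor–H–
acceptor angle ≥ 120°, common MD practice; both are configurable and every
occupancy table records the criterion used (`DataFrame.attrs["criteria"]`).
Hydrogens are attached to donor heavy atoms by a ≤ 1.2 Å distance in the
first frame when bond records are absent; donors without a covalent
hydrogen are skipped with a warning. Occupancy is a continuous fraction;
the package deliberately does not define a "persistent vs transient"
cutoff, leaving the label to the user (a report floor merely truncates the
table).

## Metadynamics

Standard, fixed-height metadynamics — not well-tempered — because the
protocol being modelled uses constant 0.6 kJ/mol hills. Two CV kinds are
implemented: a contact coordination number with the rational switching
function s(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ), defaults n = 6, m = 12, with
the removable singularity at r = r₀ evaluated as the limit n/m (and its
derivative by the corresponding series limit); and the mass-weighted
centre-of-mass separation in nm. The harmonic wall is one-sided:
κ(s − s₀)² above s₀, zero below, default κ = 1000 kJ/mol per CV-unit²
(never printed in the reference protocol; configurable).

The dynamics substrate is a BAOAB Langevin integrator. Toy systems come in
three tiers: a 1-D double well V(x) = h(x² − 1)² (analytic barrier h), a
2-D two-channel landscape V(x, y) = (x² − 1)²·C(y) whose transverse profile
C has exactly two saddles of prescribed heights separated by a high ridge
(analytic barrier min(h₁, h₂); the transverse direction is deliberately a
degenerate valley at x = ±1, which is irrelevant for grid-based barrier
extraction), and a host–guest particle pair whose CVs are computed from
coordinates so the bias force exercises the full CV chain rule.

The FES estimator is the negated bias of the final hill set, shifted to
min 0. Time-averaging the estimate over the last deposition window would
reduce standard-MTD ripple but is intentionally not implemented; the
replica spread absorbs that fluctuation instead. Barrier extraction is a
lowest-saddle (minimax) Dijkstra search over orthogonal grid neighbours
from the bound basin's minimum to the unbound region — the algorithmic form
of "inspecting the 2-D FES map", and channel-aware: with two escape routes
the lower saddle wins. Basin-to-saddle along a single projected CV is a
different convention and would give different numbers on genuinely 2-D
surfaces. Replica aggregation reports the mean and the sample (ddof = 1)
standard deviation; a single replica's sd is NaN, not 0.

The double-well benchmark runs 150,000 steps per replica (dt 4 fs, friction
5 ps⁻¹, 310 K) with hills of width 0.1 deposited every 200 steps — 750
hills, enough to fill and recross the 5 k_BT well several times. With these
conditions the replica-mean barrier lands within ~7% of the analytic value
(positive bias of order half a hill height plus minimax noise is inherent
to reading a single-snapshot standard-MTD surface); the validation
tolerance is 15% on the 3-replica mean.

Hill lists are written in the PLUMED HILLS text dialect (time, centres,
sigmas, height) for interoperability, and the reference protocol's numbers
(0.6 kJ/mol, widths 0.06/0.015 or 0.40/0.025, 4 ps pace, 3.5 nm wall,
310 K) round-trip exactly through config serialization.

## Screening

Lipinski's rule of five is applied as a hard conjunctive filter (MW ≤ 500,
HBD ≤ 5, HBA ≤ 10, logP ≤ 5) together with rotatable bonds ≤ 10; the
"one violation allowed" variant is not the default because the funnel's
purpose is eliminating poor-absorption compounds outright. Rejection
tallies count the first failing rule in the order MW, HBD, HBA, LOGP,
ROTATABLE, so tallies sum to the rejection count. "Favorable interactions"
with a target is operationalized as a present (non-missing) score in the
compounds × targets matrix — a docking pose exists; the underlying docking
is out of scope and scores arrive as input. Cutoff comparisons read "lower
than" as ≤ (scores are negative); a strict-inequality mode exists. The
ligand-based rule requires poses on at least two targets with *at least*
one score within cutoff (the stricter "exactly one" reading was rejected as
less plausible). Every selection report is re-validated against its
predicate before being returned. Ligand efficiency divides an externally
computed binding free energy by the non-hydrogen atom count.

## Synthetic data

The generators define the validation conditions and return machine-readable
ground truth. Correlated trajectories draw per-residue displacements from a
multivariate normal with the requested block structure, independently per
Cartesian component, superposed on an ideal α-helical Cα backbone (rise
1.5 Å, 100°/residue, radius 2.3 Å — chosen to be non-collinear so fitting
is well-posed). The isotropic mapping makes the dot-product covariance
exactly 3× the scalar covariance, so the target Pearson matrix equals the
scalar correlation matrix and recovery targets are exact. The implied
correlation matrix is validated positive semi-definite (eigenvalue floor
−1e-10) before sampling and the generator fails loudly on violation rather
than repairing it. Default conditions for recovery checks: 10,000 frames,
0.5 Å displacement sd, 20 residues with 6-residue blocks.

H-bond systems place a single N–H/O triple inside the criterion in exactly
round(fraction·n) frames (2.9 Å, 180°) and far outside otherwise (8 Å),
with sub-criterion jitter, so designed occupancy is recovered exactly.
Compound tables assign each rule's violations to disjoint compound sets, so
filter tallies are exactly determined. What the generators deliberately do
not emulate: force-field dynamics, anisotropic or time-correlated
fluctuations, realistic chemistry in descriptor space, or docked poses —
passing tests demonstrate estimator correctness and parameter recovery
under the stated statistical models, not feature discovery in real MD data.

## Pipeline and reproducibility

Every generator and engine is seeded; fixed-seed reruns are bit-identical
(hill lists compare equal, TSV outputs byte-identical). The YAML pipeline
writes a `manifest.json` with a stable config hash, package version, stage
outputs and wall times, plus a serialized copy of the configuration;
deterministic stages rerun from that copy reproduce their outputs exactly.
Outputs are plain TSV/JSON only.

## Known limitations

All-atom protein–ligand metadynamics, well-tempered or multiple-walker
variants, bias reweighting, residence-time kinetics beyond the barrier,
mutual-information or time-lagged correlation, network analysis on the CC
graph, π-stacking/salt-bridge detection, secondary-structure assignment,
and docking/scoring itself are out of scope. The PDB reader handles
ATOM/HETATM/MODEL records of standard fixed-width files and infers elements
from atom names when the element column is absent; exotic records are
ignored.
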