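# Methods

## Search model

`mcdock` docks a flexible ligand into a rigid receptor by minimizing a
physics-motivated scoring function over the pose state
`C = (x, y, z, a, b, c, d, ψ1…ψNrot)`: position (Å), orientation as a unit
quaternion, and one dihedral per rotatable bond. The global search runs
`thread` independent reduced-depth Monte-Carlo local searches. Each thread
draws its own uniformly random start (position uniform in the docking box,
orientation uniform on the quaternion sphere, torsions uniform in (−π, π]),
which makes the threads a partition of the conformation space into
subspaces explored in parallel, and then iterates `search_depth` times:
mutate exactly one POT block, BFGS-minimize, metropolis-accept, and on
acceptance BFGS-minimize once more. The first iteration of every thread
accepts unconditionally so no thread stays at its unoptimized start. The
metropolis rule accepts an optimized candidate at energy `eopt` against the
current energy `e0` with probability 1 if it improves and
`exp((e0 − eopt)/1.2)` otherwise; the 1.2 kcal/mol constant plays the role
of the annealing temperature. Rejected candidates are always compared
against the energy of the current accepted conformation.

Per-thread randomness comes from counter-based substreams
(`SeedSequence(master_seed, spawn_key=(thread_index,))`), so every thread's
trajectory is a pure function of `(master_seed, thread_index)`. Results are
therefore identical under any execution order or degree of parallelism; the
implementation runs threads serially, which is the portable realization of
that concurrency contract (no GPU machinery is modeled).

## Kinematics

Ligands are PDBQT torsion trees. The recursive tree is flattened once into
a depth-first node list plus a boolean children map (entry (i, j) true iff
node j is a child of node i; parents always precede children), and the
forward kinematics is an iterative pass over that list: each non-root
node's member atoms and descendants rotate by its torsion about the current
parent→child bond axis (right-hand rule), after which the whole ligand is
rotated by the quaternion about the root-atom centroid and translated to
the position. The rotation center for the rigid body is unspecified in the
underlying algorithm; the root centroid is this package's choice and keeps
position mutations well-scaled. The equivalence of the iterative pass with
a plain recursive traversal is enforced by a property test against an
independent recursive implementation (1e-12 Å on random trees).

## Scoring

`e = einter + eintra`, both in the published AutoDock Vina functional form:
weighted gauss(width 0.5), gauss(offset 3, width 2), quadratic repulsion,
hydrophobic ramp (1 → 0 over surface distance 0.5–1.5 Å) and H-bond ramp
(1 → 0 over −0.7–0 Å), evaluated on surface distance `d = r − Ri − Rj`
with an 8 Å center-center cutoff. Weights and the per-type radius /
hydrophobicity / donor / acceptor table are module-level configuration
(`mcdock.scoring.TERM_WEIGHTS`, `ATOM_KINDS`). Hydrogen types carry no
interaction terms. Two simplifications relative to a full chemistry
pipeline: carbon types are always treated as hydrophobic (bonding-dependent
reassignment is not modeled), and donor/acceptor status is read directly
from the AutoDock type rather than from bonded hydrogens.

Each pair term is *shifted* by its value at the cutoff, so the potential is
exactly zero (and continuous) at 8 Å instead of truncating with a step of a
few thousandths of a kcal/mol. This is this package's choice; it keeps
grid values continuous as receptor atoms cross the cutoff sphere and costs
one constant per type pair.

`einter` uses per-atom-type grid maps over the docking box (default spacing
0.375 Å, the AutoDock-family convention; lattice = box plus one cell of
margin) with 8-corner trilinear interpolation. Points leaving the lattice
hull are clamped and charged a quadratic penalty of 1 kcal/mol/Å² per axis,
which keeps the optimizer inside the box with finite, differentiable
energies. `eintra` sums pairs that are ≥ 4 bonds apart and in different
rigid bodies (1-2, 1-3, 1-4 exclusions); bonds are inferred from reference
geometry (≤ 1.9 Å heavy–heavy, ≤ 1.3 Å to hydrogen) plus the declared
branch axes.

The gradient over the `(7 + Nrot)` vector is assembled from per-atom
Cartesian forces through the kinematic chain: net force for the position
block, contraction with the four rotation-matrix derivatives for the
quaternion block (the quaternion is kept as 4 raw coordinates, matching the
search's parameterization, rather than a 3-dimensional tangent space), and
axis torques of each node's subtree for the torsions. It matches central
finite differences to ~1e-9 relative error away from the measure-zero ramp
kinks and grid cell faces, where the finite-difference reference itself is
invalid.

The conformational-entropy damping `1/(1 + 0.05846·Nrot)` is
pose-independent, so it is applied only to final reported scores (from the
intermolecular part), never during search, where it could not change any
ordering.

## Optimizer

Inverse-Hessian BFGS: `B0⁻¹ = identity` per call, standard rank-two update,
guarded by `sᵀy > 1e-12·|s||y|` (the update divides by `sᵀy`; degenerate
steps leave the matrix unchanged). At the first applied update the identity
seed is rescaled by `sᵀy/yᵀy` (Nocedal & Wright eq. 6.20), which adapts the
step length to the local gradient scale — important here because threads
often start in the flat long-range tail of the potential. The exact line
minimization is replaced by Armijo backtracking (c1 = 1e-4, halving, ≤ 10
trials); if a quasi-Newton direction fails the line search entirely, the
Hessian is reset and steepest descent is tried once before giving up. The
quaternion block is re-normalized after every accepted step (additive
updates leave the unit sphere). Default budget 30 iterations per call,
configurable; the minimizer returns its best-ever iterate, so it never
returns a higher energy than it was given.

Host-side refinement re-optimizes the top 20 clustered poses against the
*grid-free* intermolecular energy (direct receptor pair sums, removing
interpolation error) with a doubled per-call cap, restarting until the
energy stops improving (< 1e-9 kcal/mol between restarts), so refinement is
idempotent to the optimizer tolerance. Clustering sorts all thread bests
by energy (ties broken by thread index) and greedily keeps poses at least
1.0 Å RMSD apart — the AutoDock-family clustering radius; conformational
symmetry is not considered. RMSD is computed without re-superposition and
without symmetry correction, as in standard redocking evaluation.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `thread` | 8000 | independent docking threads; 8000 is the converged setting for medium/large ligands (desk-scale runs use fewer; the CLI warns above thread×depth = 1e5) |
| `search_depth` | heuristic | per-thread iterations; `max(1, floor(0.24·Natom + 0.29·Nrot − 3.41))` |
| `metropolis_constant` | 1.2 kcal/mol | acceptance temperature |
| `k_out` | 20 | poses refined and written |
| position mutation amplitude | 2 Å | per-axis uniform displacement, clamped to the box |
| grid spacing | 0.375 Å | trilinear lattice resolution |
| dedup RMSD | 1.0 Å | clustering radius |
| BFGS iterations | 30 / call | 60 during grid-free refinement |

`split_depth(total, n)` gives the per-thread depth that keeps
`thread × depth` near a fixed total budget (nearest integer, half up),
for trading thread count against depth at constant work.

## Synthetic fixtures

`make_planted_complex(natom, nrot, seed)` builds a deterministic toy
complex whose global-minimum pose is known by construction: a zig-zag
chain ligand (rigid root plus `nrot` nested two-atom branches — one atom on
each rotation axis, one off-axis so no torsion is a null coordinate;
`natom ≥ 2·nrot + 2`), first atom a nitrogen donor, docked in a groove of
carbon atoms at near-optimal contact distance with an OA acceptor cap at
the nitrogen end. The cap breaks the chain's end-to-end flip symmetry so
recovery is judged by plain RMSD. Candidate groove atoms that would clash
with the planted ligand are dropped, so the planted pose sits in a purely
attractive pocket. The seed jitters receptor atoms by ±0.05 Å, giving
distinct but equivalent pockets. Generation optionally verifies that the
planted pose scores below 10⁴ random conformations.

What the fixture does *not* emulate: real chemistry (bond orders,
protonation, partial charges are zero), receptor flexibility, solvent,
ring conformers, or the pose degeneracy of symmetric real ligands. Passing
recovery tests therefore demonstrates the correctness of the search,
scoring and refinement machinery on a known funnel — not docking accuracy
on real complexes.

`make_ranked_universe(n, overlap, seed)` builds two rankings of `n`
synthetic compound ids whose top-(n/10) Jaccard index approximates
`overlap`, for exercising the virtual-screening comparison utilities.

## Verification problem sizes

The test and acceptance workloads use the (12 atoms, 2 torsions) planted
complex: gradient checks at 100 random states (h = 1e-5), pose recovery
with 64 threads at heuristic depth over 20 master seeds (success: minimum
RMSD over the top-20 refined poses < 2 Å), and the fixed-budget trade-off
comparison at 10×28 vs 100×3 thread×depth — a 1/80th-scale version of the
classic 22,365-step serial budget, with best energies compared at the
0.5 kcal/mol score-comparability margin. These sizes were chosen so the
entire verification runs in minutes on one CPU while still exercising
every stage end to end.

## Known limitations

- Receptor is strictly rigid; no flexible side chains.
- AutoDock atom typing is table-driven; no bonding analysis.
- RMSD is not symmetry-corrected, which would over-penalize symmetric real
  ligands (irrelevant for the asymmetric fixtures).
- The 7-component quaternion parameterization (rather than a 6-dof tangent
  space) makes the Hessian singular along the quaternion norm direction;
  re-normalization after each step handles this in practice.
- Hardware acceleration is out of scope: `acceleration(t_ref, t_new)` is a
  reporting utility for runtime ratios, not a performance claim.
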