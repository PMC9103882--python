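"""Host-side post-processing: clustering, refinement, comparison metrics.

All thread results are pooled, sorted by energy and greedily deduplicated by
pairwise RMSD; the top poses are then re-optimized against the *grid-free*
intermolecular energy (direct receptor pair sums) with a doubled iteration
budget, which removes trilinear-interpolation error from the final answers.

Also hosts the small reporting utilities used when comparing two docking or
screening runs: the top-i Jaccard index of two ranked compound lists and the
runtime acceleration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bfgs import bfgs_minimize
from .conformation import FlatLigand, rmsd
from .errors import EmptyInputError, ParameterError
from .pdbqt import Receptor
from .scoring import DirectScorer, ScoredPose

__all__ = [
    "PoseTable",
    "cluster_and_sort",
    "refine_top",
    "jaccard_top_i",
    "acceleration",
    "write_ranked_scores",
]

DEFAULT_DEDUP_RMSD = 1.0  # Å, AutoDock-family clustering radius


@dataclass(frozen=True)
class PoseTable:
    """Cluster representatives in ascending energy order.

    Invariants: energies non-decreasing; every retained pair of poses is at
    least ``dedup_rmsd`` apart in coordinate RMSD.
    """

    poses: tuple[ScoredPose, ...]
    dedup_rmsd: float

    def __len__(self):
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i):
        return self.poses[i]


def _greedy_dedup(poses, dedup_rmsd: float):
    kept: list[ScoredPose] = []
    for pose in poses:
        if all(rmsd(pose.coords, k.coords) >= dedup_rmsd for k in kept):
            kept.append(pose)
    return kept


def cluster_and_sort(
    results, dedup_rmsd: float = DEFAULT_DEDUP_RMSD
) -> PoseTable:
    """Pool thread results, sort by ascending energy, deduplicate by RMSD.

    Ties in energy are broken by thread index, making the output stable.  A
    pose is kept iff its RMSD to every already-kept pose is at least
    ``dedup_rmsd``.
    """
    results = list(results)
    if not results:
        raise EmptyInputError("cluster_and_sort needs at least one thread result")
    ranked = sorted(results, key=lambda r: (r.best_pose.e, r.thread_index))
    kept = _greedy_dedup((r.best_pose for r in ranked), dedup_rmsd)
    return PoseTable(tuple(kept), dedup_rmsd)


def refine_top(
    table: PoseTable,
    flat: FlatLigand,
    receptor: Receptor,
    k: int = 20,
    bfgs_max_iters: int = 60,
) -> PoseTable:
    """Re-optimize the top ``min(k, len(table))`` poses grid-free.

    Each pose is BFGS-minimized under the direct (interpolation-free)
    energy with a doubled per-call iteration cap, restarting (fresh identity
    inverse Hessian) until the energy stops improving, so the refined pose
    is stationary and a second refinement is a no-op to within the optimizer
    tolerance.  Within the grid-free metric the energy never increases.  The
    refined table is re-sorted and re-deduplicated so the PoseTable
    invariants still hold.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    scorer = DirectScorer(flat, receptor)
    refined: list[ScoredPose] = []
    for i, pose in enumerate(table):
        if i >= k:
            refined.append(pose)
            continue
        c_opt = pose.conformation
        e_prev = np.inf
        for _ in range(50):
            c_opt, e = bfgs_minimize(scorer, c_opt, bfgs_max_iters)
            if e_prev - e < 1e-9:
                break
            e_prev = e
        e, einter, eintra, coords = scorer.energy(c_opt.as_vector())
        refined.append(ScoredPose(c_opt, coords, e, einter, eintra))
    refined.sort(key=lambda p: p.e)
    kept = _greedy_dedup(refined, table.dedup_rmsd)
    return PoseTable(tuple(kept), table.dedup_rmsd)


def jaccard_top_i(scores_a, scores_b, i: int) -> float:
    """Jaccard similarity of the top-``i`` sets of two ranked id lists:
    ``|A∩B| / |A∪B|`` over the first ``i`` entries of each."""
    if i < 1:
        raise ParameterError("i must be >= 1")
    top_a = set(scores_a[:i])
    top_b = set(scores_b[:i])
    union = top_a | top_b
    if not union:
        raise ParameterError("both rankings are empty")
    return len(top_a & top_b) / len(union)


def acceleration(t_ref: float, t_new: float) -> float:
    """Runtime acceleration ratio ``t_ref / t_new`` (both in seconds)."""
    if t_ref <= 0 or t_new <= 0:
        raise ParameterError("runtimes must be positive")
    return t_ref / t_new


def write_ranked_scores(ids, scores) -> str:
    """Tab-separated ranked score table (compound id, score) for the
    virtual-screening comparison workflow."""
    if len(ids) != len(scores):
        raise ParameterError("ids and scores must have equal length")
    order = sorted(range(len(ids)), key=lambda k: scores[k])
    lines = [f"{ids[k]}\t{scores[k]:.3f}" for k in order]
    return "\n".join(lines) + ("\n" if lines else "")
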