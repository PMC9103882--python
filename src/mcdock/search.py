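"""Reduced-depth Monte-Carlo iterated local search.

The global search runs many independent *docking threads*.  Each thread
starts from its own uniformly random conformation — its representative of a
subspace of the full conformation space — and performs ``search_depth``
iterations of {mutate one POT block; BFGS-optimize and score; metropolis
accept; on acceptance, BFGS-optimize once more}.  Because every thread
depends only on its own counter-based random stream, keyed by
``(master_seed, thread_index)``, results are bitwise identical regardless of
execution order or degree of actual parallelism; threads here run serially,
which is the portable realization of that concurrency contract.

Splitting a fixed total iteration budget over more threads with
proportionally smaller depth explores an equivalent conformation space: this
is the trade the heuristic depth formula and :func:`split_depth` manage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bfgs import bfgs_minimize
from .conformation import (
    Conformation,
    FlatLigand,
    MutationParams,
    mutate,
    random_conformation,
)
from .errors import ParameterError
from .pdbqt import DockingBox
from .scoring import GridCache, GridScorer, ScoredPose

__all__ = [
    "SearchParams",
    "ThreadResult",
    "metropolis_probability",
    "heuristic_search_depth",
    "split_depth",
    "run_docking_thread",
    "run_search",
]


@dataclass(frozen=True)
class SearchParams:
    """Hyperparameters of the parallel search.

    ``thread`` is the number of independent docking threads (default 8000,
    the converged setting for medium/large complexes); ``search_depth`` is
    the per-thread iteration count, resolved by the heuristic formula when
    left as None.
    """

    thread: int = 8000
    search_depth: int | None = None
    metropolis_constant: float = 1.2
    k_out: int = 20
    master_seed: int = 0
    mutation: MutationParams = field(default_factory=MutationParams)
    bfgs_max_iters: int = 30

    def __post_init__(self):
        if self.thread < 1:
            raise ParameterError("thread must be >= 1")
        if self.search_depth is not None and self.search_depth < 1:
            raise ParameterError("search_depth must be >= 1 once set")
        if self.metropolis_constant <= 0:
            raise ParameterError("metropolis_constant must be positive")

    def resolve_depth(self, natom: int, nrot: int) -> int:
        if self.search_depth is not None:
            return self.search_depth
        return heuristic_search_depth(natom, nrot)


@dataclass(frozen=True)
class ThreadResult:
    """Outcome of one docking thread: its best-ever pose and acceptance count."""

    thread_index: int
    best_pose: ScoredPose
    n_accepted: int


def metropolis_probability(
    e0: float, eopt: float, constant: float = 1.2
) -> float:
    """Acceptance probability of an optimized candidate at energy ``eopt``
    against the current energy ``e0``: 1 when the candidate improves,
    ``exp((e0 - eopt)/constant)`` otherwise."""
    if e0 > eopt:
        return 1.0
    return float(math.exp((e0 - eopt) / constant))


def heuristic_search_depth(natom: int, nrot: int) -> int:
    """Per-thread search depth fitted to ligand size:
    ``max(1, floor(0.24·Natom + 0.29·Nrot − 3.41))``."""
    if natom < 1 or nrot < 0:
        raise ParameterError("need natom >= 1 and nrot >= 0")
    return max(1, math.floor(0.24 * natom + 0.29 * nrot - 3.41))


def split_depth(total_steps: int, n_threads: int) -> int:
    """Per-thread depth that keeps ``thread × depth`` near a fixed total:
    nearest integer to total/threads, half rounded up, at least 1."""
    if n_threads < 1 or total_steps < n_threads:
        raise ParameterError("need total_steps >= n_threads >= 1")
    return max(1, math.floor(total_steps / n_threads + 0.5))


def _thread_rng(master_seed: int, thread_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(thread_index,))
    )


def run_docking_thread(
    flat: FlatLigand,
    cache: GridCache,
    box: DockingBox,
    params: SearchParams,
    thread_index: int,
    scorer: GridScorer | None = None,
) -> ThreadResult:
    """One reduced-depth iterated local search.

    The first loop iteration always accepts its candidate, guaranteeing the
    thread leaves its random start; afterwards acceptance is by the
    metropolis rule against the current accepted conformation's energy.  An
    accepted conformation is optimized a second time, and that result
    replaces it only if it does not increase the energy.  The best energy
    ever scored in the thread is tracked and returned.
    """
    if scorer is None:
        scorer = GridScorer(flat, cache)
    depth = params.resolve_depth(flat.natom, flat.nrot)
    rng = _thread_rng(params.master_seed, thread_index)
    current = random_conformation(box, flat.nrot, rng)
    e_cur = math.inf
    best_c: Conformation | None = None
    best_e = math.inf
    n_accepted = 0

    for step in range(depth):
        cand = mutate(current, params.mutation, rng, box)
        cand, e_cand = bfgs_minimize(scorer, cand, params.bfgs_max_iters)
        if e_cand < best_e:
            best_c, best_e = cand, e_cand
        p = metropolis_probability(e_cur, e_cand, params.metropolis_constant)
        if step == 0 or rng.random() < p:
            n_accepted += 1
            current, e_cur = cand, e_cand
            again, e_again = bfgs_minimize(scorer, current, params.bfgs_max_iters)
            if e_again < best_e:
                best_c, best_e = again, e_again
            if e_again <= e_cur:
                current, e_cur = again, e_again

    e, einter, eintra, coords = scorer.energy(best_c.as_vector())
    pose = ScoredPose(best_c, coords, e, einter, eintra)
    return ThreadResult(thread_index, pose, n_accepted)


def run_search(
    flat: FlatLigand,
    cache: GridCache,
    box: DockingBox,
    params: SearchParams,
) -> list[ThreadResult]:
    """Run all docking threads and return their results in thread order."""
    scorer = GridScorer(flat, cache)
    return [
        run_docking_thread(flat, cache, box, params, i, scorer=scorer)
        for i in range(params.thread)
    ]
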