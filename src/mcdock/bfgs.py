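"""Quasi-Newton minimization of the scoring function.

Maintains an approximate inverse Hessian ``Binv`` (initialized to the
identity) updated by the standard rank-two inverse-BFGS correction, with a
curvature guard on ``sᵀy`` so degenerate steps leave the matrix unchanged.
The exact line minimization of the search direction is replaced by Armijo
backtracking (c1 = 1e-4, step halving, at most 10 trials), which preserves
the descent contract while staying cheap.

The docking wrapper works on the raw (7 + Nrot) pose vector and re-normalizes
the quaternion block after every accepted step; additive updates would
otherwise drift off the unit sphere.  Each call starts from a fresh identity
``Binv``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conformation import Conformation

logger = logging.getLogger(__name__)

__all__ = ["bfgs_update", "line_search", "minimize", "bfgs_minimize", "BfgsResult"]

_ARMIJO_C1 = 1e-4
_MAX_LINE_TRIALS = 10
_CURVATURE_GUARD = 1e-12


def bfgs_update(Binv: np.ndarray, s_k: np.ndarray, y_k: np.ndarray) -> np.ndarray:
    """Rank-two inverse-Hessian update.

    Returns the updated matrix, which is symmetric and satisfies the secant
    condition ``Binv' @ y_k = s_k``.  When the curvature ``s_kᵀy_k`` is below
    the guard the update is skipped and ``Binv`` is returned unchanged.
    """
    sy = float(s_k @ y_k)
    guard = _CURVATURE_GUARD * np.linalg.norm(s_k) * np.linalg.norm(y_k)
    if sy <= guard:
        logger.debug("BFGS update skipped: curvature %.3e below guard", sy)
        return Binv
    By = Binv @ y_k
    yBy = float(y_k @ By)
    ss = np.outer(s_k, s_k)
    Bys = np.outer(By, s_k)
    out = Binv + (sy + yBy) / sy**2 * ss - (Bys + Bys.T) / sy
    return 0.5 * (out + out.T)  # keep exactly symmetric against roundoff


def line_search(f, x: np.ndarray, fx: float, grad: np.ndarray, p: np.ndarray):
    """Armijo backtracking along ``p`` from ``x``.

    If ``p`` is not a descent direction it is reset to the steepest-descent
    direction first.  Tries α in {1, 1/2, 1/4, ...} (10 trials) and returns
    ``(alpha, p, f_trial)`` for the first α satisfying
    ``f(x + αp) ≤ f(x) + 1e-4 · α · gradᵀp``; α = 0 signals failure.
    """
    gp = float(grad @ p)
    if gp >= 0.0:
        p = -grad
        gp = float(grad @ p)
        if gp >= 0.0:  # zero gradient: nowhere to go
            return 0.0, p, fx
    alpha = 1.0
    for _ in range(_MAX_LINE_TRIALS):
        f_trial = f(x + alpha * p)
        if f_trial <= fx + _ARMIJO_C1 * alpha * gp:
            return alpha, p, f_trial
        alpha *= 0.5
    return 0.0, p, fx


@dataclass
class BfgsResult:
    x: np.ndarray
    fun: float
    n_iters: int
    converged: bool


def minimize(
    f,
    grad_f,
    x0: np.ndarray,
    max_iters: int = 30,
    gtol: float = 1e-6,
    poststep=None,
) -> BfgsResult:
    """BFGS-minimize a smooth function from ``x0``.

    ``f(x) -> float`` and ``grad_f(x) -> (f, grad)`` evaluate the objective;
    ``poststep`` optionally projects each accepted iterate back onto a
    constraint manifold (used for quaternion re-normalization).  Terminates
    on the iteration budget, gradient norm below ``gtol``, or a failed line
    search; the best iterate ever seen is returned, so the result never
    exceeds the starting value.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx, g = grad_f(x)
    best_x, best_f = x.copy(), fx
    n = len(x)
    Binv = np.eye(n)
    k = 0
    converged = False
    first_update = True
    while k < max_iters:
        if np.linalg.norm(g) < gtol:
            converged = True
            break
        p = -Binv @ g
        alpha, p, f_new = line_search(f, x, fx, g, p)
        if alpha == 0.0:
            # stale curvature can make the quasi-Newton direction useless;
            # retry once along steepest descent with a reset Hessian
            if not np.array_equal(p, -g):
                Binv = np.eye(n)
                alpha, p, f_new = line_search(f, x, fx, g, -g)
            if alpha == 0.0:
                break
        x_new = x + alpha * p
        if poststep is not None:
            x_new = poststep(x_new)
        f_new, g_new = grad_f(x_new)
        s = x_new - x
        y = g_new - g
        if first_update:
            # scale the identity seed to the secant curvature before the
            # first rank-two correction (Nocedal & Wright eq. 6.20); this
            # adapts the step length to the local gradient scale
            sy, yy = float(s @ y), float(y @ y)
            if sy > 0 and yy > 0:
                Binv = (sy / yy) * Binv
            first_update = False
        Binv = bfgs_update(Binv, s, y)
        x, fx, g = x_new, f_new, g_new
        if fx < best_f:
            best_x, best_f = x.copy(), fx
        k += 1
    return BfgsResult(best_x, best_f, k, converged)


def _renormalize_quaternion(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[3:7] /= np.linalg.norm(out[3:7])
    return out


def bfgs_minimize(scorer, c0: Conformation, max_iters: int = 30):
    """Minimize the docking energy from a starting conformation.

    ``scorer`` is a :class:`~mcdock.scoring.GridScorer` or
    :class:`~mcdock.scoring.DirectScorer`.  Returns ``(Conformation, energy)``
    with energy ≤ the starting energy.
    """
    res = minimize(
        lambda x: scorer.energy(x)[0],
        scorer.energy_and_gradient,
        c0.as_vector(),
        max_iters=max_iters,
        poststep=_renormalize_quaternion,
    )
    return Conformation.from_vector(res.x), res.fun
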