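"""Sequential minimal optimization (SMO) for the weighted SVM dual.

Solves

    min_a  1/2 a^T Q a - 1^T a
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0

where ``Q_ij = y_i y_j <x_i, x_j>_{V^-1}`` is positive semidefinite
(``Q = diag(y) A A^T diag(y)`` with ``A = X V^{-1/2}``).  Working pairs are
chosen by the maximal-violating-pair rule and each two-variable subproblem
is solved in closed form along the equality-feasible direction.  The hot
loop is JIT-compiled; a step-wise pure-NumPy implementation of the same
rules (`max_violating_pair`, `two_variable_update`) is exposed for
inspection and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "DualSolution",
    "QpProblem",
    "SmoState",
    "max_violating_pair",
    "two_variable_update",
    "solve",
]

# Number of pair updates between full gradient recomputations (caps
# floating-point drift of the incrementally maintained gradient).
GRADIENT_REFRESH_EVERY = 4000

# alpha magnitude at which an unbounded (hard-margin, non-separable) dual
# is declared divergent.
_ALPHA_CAP = 1e12

# Full Q is materialized up to this many samples; above it rows are
# computed on demand from the weighted feature factor.
DENSE_LIMIT = 2000


@dataclass
class DualSolution:
    """Solution of one weighted dual QP."""

    alpha: np.ndarray
    dual_objective: float
    n_passes: int
    converged: bool
    max_kkt_violation: float


class QpProblem:
    """One dual QP instance: labels, box constraint and the Q matrix.

    ``Q`` is held either as a dense cached matrix (small problems) or as a
    factor ``A`` with ``Q = diag(y) A A^T diag(y)`` whose rows are computed
    on demand.
    """

    def __init__(self, *, labels, box_c=np.inf, tol=1e-6,
                 q_matrix=None, factor=None):
        self.labels = np.asarray(labels, dtype=np.float64).ravel()
        if not np.isin(self.labels, (-1.0, 1.0)).all():
            raise ValueError("labels must be -1/+1")
        if box_c <= 0:
            raise ValueError("box_c must be positive (np.inf for hard margin)")
        if tol <= 0:
            raise ValueError("tol must be positive")
        if (q_matrix is None) == (factor is None):
            raise ValueError("provide exactly one of q_matrix or factor")
        self.box_c = float(box_c)
        self.tol = float(tol)
        self._q = None if q_matrix is None else np.asarray(q_matrix, dtype=np.float64)
        self._factor = None if factor is None else np.asarray(factor, dtype=np.float64)
        m = self.labels.shape[0]
        if self._q is not None and self._q.shape != (m, m):
            raise ValueError("q_matrix shape mismatch")
        if self._factor is not None and self._factor.shape[0] != m:
            raise ValueError("factor row count mismatch")

    @classmethod
    def from_weighted_features(cls, a_factor, labels, box_c=np.inf, tol=1e-6,
                               dense_limit=DENSE_LIMIT):
        """Build the problem from ``A = X V^{-1/2}`` and labels.

        The full ``m x m`` matrix is cached when ``m <= dense_limit``.
        """
        a_factor = np.asarray(a_factor, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.float64).ravel()
        m = a_factor.shape[0]
        if m <= dense_limit:
            k = a_factor @ a_factor.T
            q = (labels[:, None] * labels[None, :]) * k
            return cls(labels=labels, box_c=box_c, tol=tol, q_matrix=q)
        return cls(labels=labels, box_c=box_c, tol=tol, factor=a_factor)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def is_dense(self) -> bool:
        return self._q is not None

    def row(self, i: int) -> np.ndarray:
        """Row i of Q."""
        if self._q is not None:
            return self._q[i]
        y = self.labels
        return y[i] * y * (self._factor @ self._factor[i])

    def full_matrix(self) -> np.ndarray:
        if self._q is not None:
            return self._q
        k = self._factor @ self._factor.T
        return (self.labels[:, None] * self.labels[None, :]) * k

    def gradient(self, alpha: np.ndarray) -> np.ndarray:
        """Fresh gradient Q a - 1."""
        alpha = np.asarray(alpha, dtype=np.float64)
        if self._q is not None:
            qa = self._q @ alpha
        else:
            z = self._factor.T @ (alpha * self.labels)
            qa = self.labels * (self._factor @ z)
        return qa - 1.0

    def objective(self, alpha: np.ndarray) -> float:
        alpha = np.asarray(alpha, dtype=np.float64)
        return float(0.5 * alpha @ (self.gradient(alpha) + 1.0) - alpha.sum())


@dataclass
class SmoState:
    """Mutable-by-replacement iterate of the SMO loop.

    ``gradient`` holds d(1/2 a^T Q a - 1^T a)/da = Q a - 1, maintained
    incrementally across pair updates.
    """

    alpha: np.ndarray
    gradient: np.ndarray
    n_passes: int = 0

    @classmethod
    def cold(cls, problem: QpProblem) -> "SmoState":
        m = problem.n
        return cls(alpha=np.zeros(m), gradient=np.full(m, -1.0), n_passes=0)


def _violation_scores(state: SmoState, problem: QpProblem):
    """Per-sample score -y_i g_i and the up/down admissible masks."""
    y, a, c = problem.labels, state.alpha, problem.box_c
    s = -y * state.gradient
    up = ((y > 0) & (a < c)) | ((y < 0) & (a > 0))
    down = ((y > 0) & (a > 0)) | ((y < 0) & (a < c))
    return s, up, down


def max_violating_pair(state: SmoState, problem: QpProblem):
    """Maximal-violating pair (i, j), or ``None`` at convergence.

    i maximizes -y_i g_i over the up-admissible set, j minimizes it over
    the down-admissible set; ``None`` is returned when the gap is <= tol
    (ties resolved to the lowest index, matching the compiled loop).
    """
    s, up, down = _violation_scores(state, problem)
    if not up.any() or not down.any():
        return None
    i = int(np.argmax(np.where(up, s, -np.inf)))
    j = int(np.argmin(np.where(down, s, np.inf)))
    if s[i] - s[j] <= problem.tol:
        return None
    return i, j


def two_variable_update(state: SmoState, problem: QpProblem, i: int, j: int) -> SmoState:
    """Closed-form optimal step for the pair (i, j), clipped to the box.

    Moves along ``d = y_i e_i - y_j e_j`` (which preserves sum a_k y_k
    exactly); with curvature ``eta = d^T Q d <= 0`` the better feasible
    endpoint is taken.  A pair with no violation leaves the state unchanged.
    """
    if i == j:
        raise ValueError("working pair must consist of two distinct indices")
    y, c = problem.labels, problem.box_c
    yi, yj = y[i], y[j]
    g = state.gradient
    fp = yi * g[i] - yj * g[j]  # directional derivative along d
    if fp >= 0.0:
        return state
    dmax_i = (c - state.alpha[i]) if yi > 0 else state.alpha[i]
    dmax_j = state.alpha[j] if yj > 0 else (c - state.alpha[j])
    dmax = min(dmax_i, dmax_j)
    if dmax <= 0.0:
        return state
    qi, qj = problem.row(i), problem.row(j)
    eta = qi[i] + qj[j] - 2.0 * yi * yj * qi[j]
    if eta > 0.0:
        delta = min(-fp / eta, dmax)
    else:
        # zero/negative curvature: objective decreases all the way, take
        # the feasible endpoint (which must then be finite)
        delta = dmax
    if not np.isfinite(delta):
        raise FloatingPointError(
            "unbounded descent direction: hard-margin dual is infeasible; "
            "use a finite box_c"
        )
    alpha = state.alpha.copy()
    alpha[i] += yi * delta
    alpha[j] -= yj * delta
    gradient = g + delta * (yi * qi - yj * qj)
    return SmoState(alpha=alpha, gradient=gradient, n_passes=state.n_passes + 1)


_MASKED = -1e308  # additive mask for inadmissible entries (finite: fastmath-safe)


@njit(cache=True)
def _mask_entry(y, alpha, c, k):  # pragma: no cover
    """Additive (0 / -huge) admissibility masks of sample k."""
    if (y[k] > 0.0 and alpha[k] < c) or (y[k] < 0.0 and alpha[k] > 0.0):
        um = 0.0
    else:
        um = _MASKED
    if (y[k] > 0.0 and alpha[k] > 0.0) or (y[k] < 0.0 and alpha[k] < c):
        dm = 0.0
    else:
        dm = _MASKED
    return um, dm


@njit(cache=True, fastmath=True)
def _score_and_reduce(y, g, upm, dnm, su, sd):  # pragma: no cover
    """su = -y*g + upm, sd = y*g + dnm; returns (max su, max sd).

    max su is the best 'up' score, max sd the negated best 'down' score;
    both loops are branch-free so they vectorize.
    """
    m = g.shape[0]
    for k in range(m):
        sv = -y[k] * g[k]
        su[k] = sv + upm[k]
        sd[k] = dnm[k] - sv
    bu = _MASKED
    bd = _MASKED
    for k in range(m):
        if su[k] > bu:
            bu = su[k]
        if sd[k] > bd:
            bd = sd[k]
    return bu, bd


@njit(cache=True)
def _first_at(arr, val):  # pragma: no cover
    for k in range(arr.shape[0]):
        if arr[k] == val:
            return k
    return -1


@njit(cache=True)
def _smo_dense(q, y, c, tol, max_updates, refresh_every, alpha_cap, alpha0):  # pragma: no cover
    m = q.shape[0]
    alpha = alpha0.copy()
    g = np.dot(q, alpha) - 1.0
    upm = np.empty(m)
    dnm = np.empty(m)
    for k in range(m):
        upm[k], dnm[k] = _mask_entry(y, alpha, c, k)
    su = np.empty(m)
    sd = np.empty(m)
    n_upd = 0
    status = 0  # 0 converged, 1 budget exhausted, 2 unbounded, 3 stalled
    viol = 0.0
    while True:
        bu, bd = _score_and_reduce(y, g, upm, dnm, su, sd)
        if bu < -1e307 or bd < -1e307:
            viol = 0.0
            break
        viol = bu + bd  # = max up-score - min down-score
        if viol <= tol:
            break
        if n_upd >= max_updates:
            status = 1
            break
        # the max of a set of doubles is attained exactly, so an equality
        # scan recovers the lowest maximizing index (same tie-break as a
        # serial strict-> search)
        i = _first_at(su, bu)
        j = _first_at(sd, bd)
        yi = y[i]
        yj = y[j]
        eta = q[i, i] + q[j, j] - 2.0 * yi * yj * q[i, j]
        fp = yi * g[i] - yj * g[j]
        dmax_i = (c - alpha[i]) if yi > 0.0 else alpha[i]
        dmax_j = alpha[j] if yj > 0.0 else (c - alpha[j])
        dmax = dmax_i if dmax_i < dmax_j else dmax_j
        if eta > 0.0:
            delta = -fp / eta
            if delta > dmax:
                delta = dmax
        else:
            delta = dmax
        if not np.isfinite(delta):
            status = 2
            break
        if delta <= 0.0:
            status = 3
            break
        alpha[i] += yi * delta
        alpha[j] -= yj * delta
        if alpha[i] > alpha_cap or alpha[j] > alpha_cap:
            status = 2
            break
        upm[i], dnm[i] = _mask_entry(y, alpha, c, i)
        upm[j], dnm[j] = _mask_entry(y, alpha, c, j)
        n_upd += 1
        if n_upd % refresh_every == 0:
            g = np.dot(q, alpha) - 1.0
        else:
            # rank-two incremental gradient update; rows of q are
            # contiguous and the loop is branch-free, so it vectorizes
            ci = yi * delta
            cj = yj * delta
            qi = q[i]
            qj = q[j]
            for k in range(m):
                g[k] += ci * qi[k] - cj * qj[k]
    return alpha, viol, n_upd, status


def _solve_rows(problem: QpProblem, max_passes: int, alpha0=None):
    # on-demand-row path for problems too large to cache Q densely
    if alpha0 is None:
        state = SmoState.cold(problem)
    else:
        state = SmoState(alpha=alpha0.copy(), gradient=problem.gradient(alpha0))
    status = 0
    viol = 0.0
    while True:
        pair = max_violating_pair(state, problem)
        if pair is None:
            viol = 0.0
            break
        i, j = pair
        s, _, _ = _violation_scores(state, problem)
        viol = float(s[i] - s[j])
        if state.n_passes >= max_passes:
            status = 1
            break
        new = two_variable_update(state, problem, i, j)
        if new.n_passes == state.n_passes:
            status = 3
            break
        state = new
        if state.alpha.max(initial=0.0) > _ALPHA_CAP:
            status = 2
            break
        if state.n_passes % GRADIENT_REFRESH_EVERY == 0:
            state = replace(state, gradient=problem.gradient(state.alpha))
    return state.alpha, viol, state.n_passes, status


def solve(problem: QpProblem, max_passes: int = 200_000, alpha0=None) -> DualSolution:
    """Run SMO to within ``problem.tol`` on the maximal KKT violation.

    ``alpha0`` optionally warm-starts the iteration from a feasible point
    (e.g. the solution of a previously reweighted problem); the default is
    the cold start alpha = 0.

    Raises
    ------
    FloatingPointError
        When the hard-margin (unbounded box) dual is detected to be
        unbounded, i.e. the data are not linearly separable.
    """
    if max_passes <= 0:
        raise ValueError("max_passes must be positive")
    if alpha0 is not None:
        alpha0 = np.asarray(alpha0, dtype=np.float64)
        if alpha0.shape[0] != problem.n:
            raise ValueError("alpha0 length mismatch")
        if (alpha0 < 0).any() or (alpha0 > problem.box_c).any():
            raise ValueError("alpha0 violates the box constraints")
    if problem.is_dense:
        start = np.zeros(problem.n) if alpha0 is None else alpha0
        alpha, viol, n_upd, status = _smo_dense(
            problem.full_matrix(), problem.labels, problem.box_c, problem.tol,
            max_passes, GRADIENT_REFRESH_EVERY, _ALPHA_CAP, start,
        )
    else:
        alpha, viol, n_upd, status = _solve_rows(problem, max_passes, alpha0)
    if status == 2:
        raise FloatingPointError(
            "dual objective is unbounded: the data are not linearly separable "
            "under a hard margin; refit with a finite box_c"
        )
    converged = status == 0
    if status == 1:
        warnings.warn(
            f"SMO pass budget ({max_passes}) exhausted with KKT violation "
            f"{viol:.3e} > tol {problem.tol:.1e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return DualSolution(
        alpha=alpha,
        dual_objective=problem.objective(alpha),
        n_passes=int(n_upd),
        converged=bool(converged),
        max_kkt_violation=float(max(viol, 0.0)),
    )
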