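"""Independent reference solvers used to cross-check the package.

These deliberately share no code with :mod:`lpsvm.smo`: the dual QP is
solved by projected gradient descent with an exact projection onto the
box-and-hyperplane feasible set (projection computed by bisection on the
hyperplane multiplier).
"""

import numpy as np


def project_feasible(z, y, box_c):
    """Euclidean projection of z onto {0 <= a <= C, sum a_k y_k = 0}.

    The projection is clip(z - lam*y, 0, C) for the lam solving
    h(lam) = sum_k y_k clip(z_k - lam*y_k, 0, C) = 0; h is nonincreasing
    in lam, so bisection converges.
    """
    c = box_c if np.isfinite(box_c) else 1e12

    def h(lam):
        return float(np.sum(y * np.clip(z - lam * y, 0.0, c)))

    lo, hi = -1.0, 1.0
    while h(lo) < 0.0:
        lo *= 2.0
        if lo < -1e15:
            raise RuntimeError("projection bracket failed")
    while h(hi) > 0.0:
        hi *= 2.0
        if hi > 1e15:
            raise RuntimeError("projection bracket failed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return np.clip(z - 0.5 * (lo + hi) * y, 0.0, c)


def projected_gradient_qp(q, y, box_c, n_iter=200_000, tol=1e-14):
    """Minimize 1/2 a^T Q a - 1^T a over the feasible set (tiny problems)."""
    m = q.shape[0]
    step = 1.0 / (np.linalg.eigvalsh(q).max() + 1e-9)
    alpha = project_feasible(np.zeros(m), y, box_c)
    for _ in range(n_iter):
        grad = q @ alpha - 1.0
        new = project_feasible(alpha - step * grad, y, box_c)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def dual_objective(q, alpha):
    return float(0.5 * alpha @ q @ alpha - alpha.sum())


def weighted_q_matrix(x, y, v):
    """Q_ij = y_i y_j x_i^T V^{-1} x_j for diagonal V = diag(v)."""
    a = x / np.sqrt(v)[None, :]
    return (y[:, None] * y[None, :]) * (a @ a.T)
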