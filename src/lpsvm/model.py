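"""Lp-penalized linear SVM fitted by iterative reweighting.

The primal problem is

    min_w  1/2 ||w||_p^p    s.t.  y_i (w^T x_i - b) >= 1,   0 < p <= 2,

optionally softened by a box constraint 0 <= alpha_i <= C on the dual
multipliers.  For p < 2 the bridge penalty is nonconvex; it is minimized
by a majorize-minimize scheme: around the current iterate w^(t) the
penalty is replaced by the quadratic surrogate 1/2 w^T V w with

    V = diag[(|w_j^(t)| + eps)^(p-2)],

whose dual is a standard weighted SVM QP

    min_a 1/2 a^T diag(Y) X V^{-1} X^T diag(Y) a - 1^T a,
    0 <= a <= C,  sum_i a_i y_i = 0,

solved by SMO (:mod:`lpsvm.smo`).  The primal weights are recovered as
w = V^{-1} X^T diag(Y) a, the bias from the support vectors via the KKT
conditions, and the loop repeats until w stabilizes.  At p = 2 the
surrogate is exact (V = I) and the procedure reduces to the ordinary
L2 SVM in a single effective step; as p decreases toward 0 the
reweighting drives small coordinates of w to (numerical) zero, which is
what makes the fit an embedded feature selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .smo import DualSolution, QpProblem, solve as smo_solve

__all__ = [
    "FitOptions",
    "LpSvmModel",
    "DualSolution",
    "penalty",
    "reweight_diag",
    "solve_weighted_dual",
    "primal_from_dual",
    "compute_bias",
    "fit_irwp",
    "decision_function",
    "predict",
    "selected_features",
]


@dataclass
class FitOptions:
    """Hyperparameters of the iteratively reweighted Lp SVM.

    Attributes
    ----------
    p
        Penalty exponent in (0, 2]; p=2 is the ridge penalty, p=1 the
        lasso, 0<p<1 the bridge penalty.
    epsilon
        Reweighting smoother: weights are (|w_j|+epsilon)^(p-2), so
        epsilon bounds the weight explosion at w_j = 0.
    box_c
        Soft-margin cap C on the dual variables; ``np.inf`` gives the
        hard margin (requires separable data).
    outer_tol
        Relative change of w at which the reweighting loop stops.
    max_outer_iters
        Cap on reweighting iterations.
    smo_tol
        KKT-violation tolerance of the inner SMO solver.
    max_smo_passes
        Cap on SMO pair updates per inner solve.
    support_threshold
        alpha cutoff defining the support set S.
    feature_threshold
        Relative |w_j| cutoff (fraction of max_j |w_j|) above which a
        feature counts as selected.
    """

    p: float = 0.8
    epsilon: float = 1e-8
    box_c: float = 10.0
    outer_tol: float = 1e-4
    max_outer_iters: int = 150
    smo_tol: float = 1e-5
    max_smo_passes: int = 200_000
    support_threshold: float = 1e-8
    feature_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 2.0:
            raise ValueError(f"p must lie in (0, 2], got {self.p}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.box_c <= 0:
            raise ValueError("box_c must be > 0 (np.inf for hard margin)")
        for name in ("outer_tol", "smo_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_outer_iters < 1 or self.max_smo_passes < 1:
            raise ValueError("iteration caps must be positive")
        if self.support_threshold < 0 or self.feature_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class LpSvmModel:
    """Fitted sparse linear SVM."""

    weights: np.ndarray
    bias: float
    p: float
    support_indices: np.ndarray
    n_outer_iters: int
    weight_trajectory: list = field(repr=False)
    converged: bool
    dual: DualSolution | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def penalty(w: np.ndarray, p: float) -> float:
    """Bridge penalty 1/2 sum_j |w_j|^p."""
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("w contains non-finite entries")
    if not 0.0 < p <= 2.0:
        raise ValueError(f"p must lie in (0, 2], got {p}")
    return float(0.5 * np.sum(np.abs(w) ** p))


def reweight_diag(w: np.ndarray, p: float, epsilon: float) -> np.ndarray:
    """Diagonal of the surrogate weight matrix V.

    Returns v with v_j = (|w_j| + epsilon)^(p-2); epsilon > 0 keeps every
    entry finite (at p < 2 the unsmoothed weight diverges as w_j -> 0).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 (division-by-zero hazard)")
    if not 0.0 < p <= 2.0:
        raise ValueError(f"p must lie in (0, 2], got {p}")
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("w contains non-finite entries")
    v = (np.abs(w) + epsilon) ** (p - 2.0)
    return v


def _check_trainable(data: Dataset) -> None:
    if data.n_samples < 2:
        raise ValueError("need at least two samples")
    if not data.has_both_classes():
        raise ValueError("training data must contain both classes")


def solve_weighted_dual(
    data: Dataset, v: np.ndarray, opts: FitOptions, alpha0: np.ndarray | None = None
) -> DualSolution:
    """Solve the weighted dual QP for a fixed reweighting diagonal v.

    ``alpha0`` optionally warm-starts SMO from a feasible dual point (the
    feasible set does not depend on v, so the previous outer iteration's
    alpha is always admissible).
    """
    _check_trainable(data)
    v = np.asarray(v, dtype=np.float64)
    if v.shape[0] != data.n_features:
        raise ValueError("v length does not match feature count")
    if not (np.isfinite(v).all() and (v > 0).all()):
        raise ValueError("v must be strictly positive and finite")
    a_factor = data.features / np.sqrt(v)[None, :]
    problem = QpProblem.from_weighted_features(
        a_factor, data.labels, box_c=opts.box_c, tol=opts.smo_tol
    )
    try:
        return smo_solve(problem, max_passes=opts.max_smo_passes, alpha0=alpha0)
    except FloatingPointError as exc:
        raise ValueError(
            "hard-margin dual is unbounded (data not linearly separable); "
            "set a finite box_c"
        ) from exc


def primal_from_dual(data: Dataset, alpha: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Recover primal weights w_j = v_j^{-1} sum_i alpha_i y_i x_ij."""
    alpha = np.asarray(alpha, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if alpha.shape[0] != data.n_samples:
        raise ValueError("alpha length does not match sample count")
    if v.shape[0] != data.n_features:
        raise ValueError("v length does not match feature count")
    return ((alpha * data.labels) @ data.features) / v


def compute_bias(data: Dataset, w: np.ndarray, alpha: np.ndarray, opts: FitOptions) -> float:
    """Bias b = mean over support vectors k of (w^T x_k - y_k).

    The support set is S = {i : alpha_i > support_threshold}; by the KKT
    complementarity each such point sits on its margin, so each term is an
    exact expression for b and the mean is taken for numerical robustness.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    support = alpha > opts.support_threshold
    if not support.any():
        raise ValueError("empty support set: no alpha exceeds support_threshold")
    margins = data.features[support] @ np.asarray(w, dtype=np.float64)
    return float(np.mean(margins - data.labels[support]))


def fit_irwp(data: Dataset, opts: FitOptions) -> LpSvmModel:
    """Fit the Lp SVM by iterative reweighting.

    Starts from w = 1 (so the first inner solve is the plain L2 SVM) and
    alternates reweighting, the dual solve, and primal/bias recovery until
    the relative change of w drops below ``outer_tol``.
    """
    _check_trainable(data)
    w = np.ones(data.n_features)
    trajectory: list[np.ndarray] = []
    converged = False
    dual: DualSolution | None = None
    bias = 0.0
    alpha0 = None
    for _ in range(opts.max_outer_iters):
        v = reweight_diag(w, opts.p, opts.epsilon)
        dual = solve_weighted_dual(data, v, opts, alpha0=alpha0)
        alpha0 = dual.alpha
        w_new = primal_from_dual(data, dual.alpha, v)
        bias = compute_bias(data, w_new, dual.alpha, opts)
        trajectory.append(w_new)
        delta = np.linalg.norm(w_new - w) / max(1.0, np.linalg.norm(w))
        w = w_new
        if delta < opts.outer_tol:
            converged = True
            break
    assert dual is not None
    if not converged:
        warnings.warn(
            f"reweighting loop did not converge within {opts.max_outer_iters} "
            "iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    support = np.flatnonzero(dual.alpha > opts.support_threshold)
    return LpSvmModel(
        weights=w,
        bias=bias,
        p=opts.p,
        support_indices=support,
        n_outer_iters=len(trajectory),
        weight_trajectory=trajectory,
        converged=converged and dual.converged,
        dual=dual,
    )


def _margins(model: LpSvmModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[-1]}"
        )
    return x @ model.weights - model.bias


def decision_function(model: LpSvmModel, x: np.ndarray) -> float:
    """Signed margin w^T x - b for a single sample."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("decision_function takes a single sample vector")
    return float(_margins(model, x))


def predict(model: LpSvmModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels sign(w^T x - b) per row; sign(0) maps to +1."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    m = _margins(model, features)
    return np.where(m >= 0.0, 1.0, -1.0)


def selected_features(model: LpSvmModel, opts: FitOptions) -> frozenset:
    """Features retained by the fit.

    A feature is selected when |w_j| exceeds ``feature_threshold`` times
    the largest |w_j|.
    """
    mags = np.abs(model.weights)
    top = mags.max(initial=0.0)
    if top == 0.0:
        raise ValueError("all weights are zero; no features can be selected")
    return frozenset(np.flatnonzero(mags > opts.feature_threshold * top).tolist())
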