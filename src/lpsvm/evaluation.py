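"""Simulation-study harness: error criteria, experiment grid, p selection.

Two criteria score a fitted sparse SVM on the synthetic benchmark:

* prediction error rate (Pe, %): misclassified fraction of a validation
  set;
* feature selection error rate (Fse, %): size of the symmetric difference
  between the selected-feature set and the known relevant set, as a
  percentage of the total feature count.  This definition is symmetric,
  bounded by 100, and zero exactly when the relevant set is recovered.

``run_experiment`` repeats, per seeded trial: generate a fresh benchmark
pool, split it, standardize on the training part, fit at every p in the
grid, and record both criteria; results are aggregated to per-cell means
and standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .model import FitOptions, LpSvmModel, fit_irwp, predict, selected_features
from .synthetic import WestonSpec, generate_weston, split, standardize

__all__ = [
    "TrialResult",
    "ExperimentSummary",
    "prediction_error_rate",
    "feature_selection_error_rate",
    "run_trials",
    "summarize",
    "run_experiment",
    "select_p",
    "plot_fse_errorbars",
]

logger = logging.getLogger(__name__)

METRICS = ("prediction_error_pct", "feature_selection_error_pct", "n_selected")


@dataclass
class TrialResult:
    """Criteria of one (trial, p, split) cell."""

    p: float
    n_train: int
    n_valid: int
    prediction_error_pct: float
    feature_selection_error_pct: float
    n_selected: int
    seed: int


@dataclass
class ExperimentSummary:
    """Tidy per-cell aggregate of an experiment grid.

    ``frame`` has columns p, n_train, n_valid, metric, mean, sd, n_trials.
    """

    frame: pd.DataFrame
    n_trials: int

    def cell(self, p: float, n_train: int, metric: str) -> tuple[float, float]:
        """(mean, sd) of a metric in one grid cell."""
        f = self.frame
        row = f[
            np.isclose(f["p"], p) & (f["n_train"] == n_train) & (f["metric"] == metric)
        ]
        if len(row) != 1:
            raise KeyError(f"no unique cell for p={p}, n_train={n_train}, {metric}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def prediction_error_rate(model: LpSvmModel, valid: Dataset) -> float:
    """Percentage of validation samples the model misclassifies."""
    if valid.n_samples == 0:
        raise ValueError("validation set is empty")
    pred = predict(model, valid.features)
    return 100.0 * float(np.mean(pred != valid.labels))


def feature_selection_error_rate(selected, relevant, n_features: int) -> float:
    """100 * |selected symmetric-difference relevant| / n_features."""
    selected = frozenset(int(j) for j in selected)
    relevant = frozenset(int(j) for j in relevant)
    for j in selected | relevant:
        if not 0 <= j < n_features:
            raise ValueError(f"feature index {j} out of range [0, {n_features})")
    return 100.0 * len(selected ^ relevant) / n_features


def _trial_seeds(master_seed: int, trial: int, split_idx: int):
    gen_seed = int(np.random.SeedSequence((master_seed, trial)).generate_state(1)[0] >> 1)
    split_seed = int(
        np.random.SeedSequence((master_seed, trial, split_idx)).generate_state(1)[0] >> 1
    )
    return gen_seed, split_seed


def run_trials(
    grid,
    splits,
    n_trials: int,
    seed: int,
    opts: FitOptions | None = None,
    n_pool: int = 1000,
    n_features: int = 100,
    trial_offset: int = 0,
) -> list[TrialResult]:
    """Per-trial results over a (p, split) grid on fresh benchmark pools.

    Each trial regenerates its own pool from a sub-seed derived from
    ``(seed, trial)``, so any prefix of trials is reproducible
    independently of ``n_trials``; ``trial_offset`` shifts the trial
    indices so that two runs can split one seed stream and their pooled
    results match a single longer run.  Failed fits are logged and
    excluded; more than 10% failures aborts the experiment.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not grid:
        raise ValueError("p grid is empty")
    opts = opts or FitOptions()
    results: list[TrialResult] = []
    n_failed = 0
    total = n_trials * len(splits) * len(grid)
    for t in range(trial_offset, trial_offset + n_trials):
        for k, (n_train, n_valid) in enumerate(splits):
            if n_train + n_valid != n_pool:
                raise ValueError(
                    f"split {n_train}+{n_valid} does not partition the pool of {n_pool}"
                )
            gen_seed, split_seed = _trial_seeds(seed, t, k)
            pool = generate_weston(
                WestonSpec(n_samples=n_pool, n_features=n_features, seed=gen_seed)
            )
            train, valid = split(pool, n_train, seed=split_seed)
            train, (valid,), _ = standardize(train, [valid])
            for p in grid:
                trial_opts = FitOptions(**{**opts.__dict__, "p": float(p)})
                try:
                    model = fit_irwp(train, trial_opts)
                    sel = selected_features(model, trial_opts)
                    results.append(
                        TrialResult(
                            p=float(p),
                            n_train=n_train,
                            n_valid=n_valid,
                            prediction_error_pct=prediction_error_rate(model, valid),
                            feature_selection_error_pct=feature_selection_error_rate(
                                sel, train.relevant_indices, train.n_features
                            ),
                            n_selected=len(sel),
                            seed=gen_seed,
                        )
                    )
                except Exception:  # noqa: BLE001 - per-trial exclusion policy
                    n_failed += 1
                    logger.exception(
                        "fit failed (trial=%d, p=%.2f, split=%d+%d); excluded",
                        t, p, n_train, n_valid,
                    )
        logger.info("trial %d/%d done", t + 1, n_trials)
    if n_failed > 0.10 * total:
        raise RuntimeError(
            f"{n_failed}/{total} fits failed (> 10%); experiment aborted"
        )
    return results


def summarize(results: list[TrialResult]) -> ExperimentSummary:
    """Aggregate trial results into per-cell means and SDs (tidy frame)."""
    if not results:
        raise ValueError("no trial results to summarize")
    raw = pd.DataFrame([r.__dict__ for r in results])
    rows = []
    for (p, n_train, n_valid), g in raw.groupby(["p", "n_train", "n_valid"]):
        for metric in METRICS:
            vals = g[metric].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "p": p,
                    "n_train": n_train,
                    "n_valid": n_valid,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "n_trials": len(vals),
                }
            )
    frame = pd.DataFrame(rows).sort_values(["n_train", "p", "metric"], ignore_index=True)
    return ExperimentSummary(frame=frame, n_trials=int(frame["n_trials"].max()))


def run_experiment(
    grid,
    splits,
    n_trials: int,
    seed: int,
    opts: FitOptions | None = None,
    n_pool: int = 1000,
    n_features: int = 100,
) -> ExperimentSummary:
    """Run the full simulation grid and aggregate (see :func:`run_trials`)."""
    return summarize(
        run_trials(grid, splits, n_trials, seed, opts, n_pool, n_features)
    )


def select_p(train: Dataset, valid: Dataset, grid, opts: FitOptions | None = None):
    """Pick p from a grid by validation error; ties go to the smaller p.

    Returns ``(best_p, model)``.  Fits that fail are skipped; an error is
    raised only if every candidate fails.
    """
    if not grid:
        raise ValueError("p grid is empty")
    opts = opts or FitOptions()
    best = None
    for p in sorted(float(p) for p in grid):
        trial_opts = FitOptions(**{**opts.__dict__, "p": p})
        try:
            model = fit_irwp(train, trial_opts)
        except Exception:  # noqa: BLE001
            logger.exception("fit failed at p=%.3f during selection", p)
            continue
        err = prediction_error_rate(model, valid)
        if best is None or err < best[0]:
            best = (err, p, model)
    if best is None:
        raise RuntimeError("every candidate p failed to fit")
    return best[1], best[2]


def plot_fse_errorbars(summary: ExperimentSummary, path) -> None:
    """Feature-selection-error means with 2-SD error bars, one line per split."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = summary.frame
    fig, ax = plt.subplots(figsize=(6, 4))
    fse = f[f["metric"] == "feature_selection_error_pct"]
    for (n_train, n_valid), g in fse.groupby(["n_train", "n_valid"]):
        g = g.sort_values("p")
        ax.errorbar(
            g["p"], g["mean"], yerr=2.0 * g["sd"],
            marker="o", capsize=3, label=f"{n_train}+{n_valid}",
        )
    ax.set_xlabel("p")
    ax.set_ylabel("feature selection error (%)")
    ax.legend(title="train+valid")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
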