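"""Stable feature selection by randomized L1-penalized logistic regression.

Stability selection repeatedly fits an L1-penalized logistic regression on
random subsamples of the rows, with each feature's penalty additionally
scaled by an independent random "weakness" draw, and keeps the features whose
coefficients are non-zero in at least a threshold fraction of resamples.

The nested variant decomposes a sensor's feature space by temporal slice,
runs stability selection within each slice group, concatenates the
group-level survivors, and runs stability selection once more on that much
smaller set — giving the sensor's final feature set.

Per-feature penalty scaling is implemented by column scaling: multiplying
column j by w_j < 1 before an L1 fit is equivalent to dividing its penalty
by w_j, and leaves the zero/non-zero pattern of the solution unchanged in
meaning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import sklearn
from scipy.special import expit
from sklearn.linear_model import LogisticRegression


@dataclasses.dataclass
class StabilityConfig:
    """Stability-selection hyperparameters (standard defaults)."""

    n_resamples: int = 100
    subsample_fraction: float = 0.75
    weakness: float = 0.5          # alpha: random per-feature penalty scale in {alpha, 1}
    threshold: float = 0.4         # pi: minimum selection frequency (inclusive)
    c: float = 1.0                 # base inverse regularization strength
    seed: int = 0
    #: "proximal" solves all resamples' L1 fits in one batched FISTA pass;
    #: "liblinear" loops over per-resample scikit-learn fits (slower, used as
    #: an independent cross-check).
    solver: str = "proximal"

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        for name in ("subsample_fraction", "weakness", "threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1]")
        if self.solver not in ("proximal", "liblinear"):
            raise ValueError(f"unknown solver {self.solver!r}")


def l1_logistic_batch(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Batched L1-penalized logistic regression via FISTA.

    Minimizes ``C * sum_i log(1 + exp(-y_i (x_i.w + b))) + ||w||_1`` with an
    unpenalized intercept, independently for every resample in the leading
    axis of ``X`` (shape (R, n, p)) and ``y`` (shape (R, n), 0/1 labels).
    The proximal soft-threshold step produces exact zeros, so the sparsity
    pattern is directly comparable to a coordinate-descent L1 fit. Returns
    coefficients of shape (R, p).
    """
    R, n, p = X.shape
    Z = np.concatenate([X, np.ones((R, n, 1))], axis=2)
    smax = np.linalg.svd(Z, compute_uv=False)[:, 0]
    step = (4.0 / (C * np.maximum(smax, 1e-12) ** 2))[:, None]
    yy = 2.0 * y - 1.0
    w = np.zeros((R, p + 1))
    v = w.copy()
    t = 1.0
    for it in range(max_iter):
        z = np.einsum("rnk,rk->rn", Z, v)
        sig = expit(-yy * z)
        g = -C * np.einsum("rn,rnk->rk", yy * sig, Z)
        w_new = v - step * g
        ww = w_new[:, :p]
        w_new[:, :p] = np.sign(ww) * np.maximum(np.abs(ww) - step, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        v = w_new + ((t - 1) / t_new) * (w_new - w)
        converged = it % 10 == 9 and np.max(np.abs(w_new - w)) < tol
        w, t = w_new, t_new
        if converged:
            break
    return w[:, :p]


@dataclasses.dataclass
class SelectionResult:
    """Selection frequencies and the surviving feature set."""

    frequency: pd.Series       # per feature, in [0, 1]
    selected: list             # features with frequency >= threshold
    stage: str = "group"


def _stratified_subsample(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Subsample rows without replacement, preserving class balance so both
    classes stay represented."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * len(members))))
        idx.append(rng.choice(members, size=min(k, len(members)), replace=False))
    return np.sort(np.concatenate(idx))


def stability_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: StabilityConfig | None = None,
    rng: np.random.Generator | None = None,
    stage: str = "group",
) -> SelectionResult:
    """Randomized logistic regression over resamples of (standardized) X.

    Columns containing no variation are never selected. A single-class label
    vector yields an empty selection with a warning.
    """
    config = config or StabilityConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = list(range(Xv.shape[1]))
    y = np.asarray(y).astype(int)
    n, p = Xv.shape
    freq = pd.Series(np.zeros(p), index=_as_index(columns))
    if p == 0:
        return SelectionResult(frequency=freq, selected=[], stage=stage)
    if len(np.unique(y)) < 2:
        warnings.warn("stability_select: single-class labels, empty selection")
        return SelectionResult(frequency=freq, selected=[], stage=stage)
    nonconstant = Xv.std(axis=0) > 0
    if not nonconstant.any():
        return SelectionResult(frequency=freq, selected=[], stage=stage)
    R = config.n_resamples
    rows = np.stack([_stratified_subsample(y, config.subsample_fraction, rng) for _ in range(R)])
    weights = np.where(rng.random((R, p)) < 0.5, config.weakness, 1.0)
    counts = np.zeros(p)
    if config.solver == "proximal":
        Xs = Xv[rows] * weights[:, None, :]
        coefs = l1_logistic_batch(Xs[:, :, nonconstant], y[rows].astype(float), config.c)
        counts[nonconstant] = (np.abs(coefs) > 1e-10).sum(axis=0)
    else:
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=config.c)
        with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in range(R):
                Xs = Xv[rows[r]] * weights[r]
                est.fit(Xs[:, nonconstant], y[rows[r]])
                coef = np.zeros(p)
                coef[nonconstant] = est.coef_[0]
                counts += np.abs(coef) > 1e-10
    freq[:] = counts / config.n_resamples
    selected = [c for c, f in freq.items() if f >= config.threshold]
    return SelectionResult(frequency=freq, selected=selected, stage=stage)


def _as_index(columns) -> pd.Index:
    if columns and isinstance(columns[0], tuple):
        return pd.MultiIndex.from_tuples(columns)
    return pd.Index(columns)


def nested_select(
    X: pd.DataFrame,
    y: np.ndarray,
    config: StabilityConfig | None = None,
    group_level: str | int = "slice",
) -> tuple[list, pd.DataFrame]:
    """Two-stage nested selection for one sensor's feature matrix.

    ``X`` has MultiIndex columns with a temporal-slice level; stage 1 runs
    stability selection within each slice group, stage 2 on the concatenated
    stage-1 survivors. Returns the final selected columns (possibly empty)
    and a report table ``(column levels..., frequency, stage, selected)``.

    Group results use independent child seeds keyed by group order, so the
    outcome does not depend on dict iteration order.
    """
    config = config or StabilityConfig()
    if not isinstance(X.columns, pd.MultiIndex):
        raise ValueError("nested_select expects MultiIndex columns with a slice level")
    groups = X.columns.get_level_values(group_level)
    survivors: list = []
    report_rows = []
    for gi, g in enumerate(pd.unique(groups)):
        sub = X.loc[:, groups == g]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, gi]))
        res = stability_select(sub, y, config, rng, stage="group")
        survivors.extend(res.selected)
        for col, f in res.frequency.items():
            report_rows.append((*col, float(f), "group", col in set(res.selected)))
    if survivors:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        final = stability_select(X[survivors], y, config, rng, stage="global")
        final_selected = final.selected
        for col, f in final.frequency.items():
            report_rows.append((*col, float(f), "global", col in set(final_selected)))
    else:
        final_selected = []
    names = list(X.columns.names) if X.columns.names[0] else ["sensor", "slice", "feature"]
    report = pd.DataFrame(
        report_rows, columns=[*names, "frequency", "stage", "selected"]
    )
    return final_selected, report
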