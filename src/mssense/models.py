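"""1-sensor classifiers, the late-fusion ensemble, and the sensor ablation.

For each sensor, logistic regression and gradient boosting candidates are
trained on the fold-selected features; the configuration with the best
pooled out-of-fold F1 becomes that sensor's model, and its positive-class
detection probabilities are carried forward. The six probability columns are
stacked into a meta-feature matrix and fed to an AdaBoost ensemble with a
gradient-boosting base estimator; its n_estimators is tuned on the same
leave-5-participants-out cross-validation. An ablation trains one ensemble
per sensor combination (all subsets of size >= 2: 57 combinations for six
sensors) under the shared fold plan.

Stacking discipline: the meta-features used to *train* an ensemble in a fold
come from an inner leave-5-participants-out pass within that fold's training
participants, never from models that saw the fold's test participants.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .constants import SENSORS


@dataclasses.dataclass
class ModelConfig:
    """Candidate grids for the 1-sensor models."""

    lr_c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    gb_n_estimators: tuple[int, ...] = (50, 100)
    gb_max_depths: tuple[int, ...] = (2, 3)
    gb_learning_rate: float = 0.1


@dataclasses.dataclass
class EnsembleConfig:
    """AdaBoost-over-gradient-boosting ensemble configuration."""

    n_estimators_grid: tuple[int, ...] = (5, 10, 20, 30, 50)
    base_n_estimators: int = 30
    base_max_depth: int = 3
    base_learning_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_estimators_grid or any(g < 1 for g in self.n_estimators_grid):
            raise ValueError("n_estimators_grid must be non-empty positive integers")


def candidate_names(config: ModelConfig) -> list[str]:
    names = [f"lr_C={c:g}" for c in config.lr_c_grid]
    names += [
        f"gb_n={n}_d={d}" for d in config.gb_max_depths for n in config.gb_n_estimators
    ]
    return names


def fit_candidates(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ModelConfig,
    seed: int,
) -> dict[str, np.ndarray]:
    """Positive-class test probabilities for every candidate configuration.

    With no features (empty selection) every candidate degenerates to a
    constant model emitting the training prevalence. Gradient-boosting tree
    counts are evaluated from a single staged fit per depth.
    """
    prev = float(np.mean(y_train))
    out: dict[str, np.ndarray] = {}
    if X_train.shape[1] == 0 or len(np.unique(y_train)) < 2:
        return {name: np.full(len(X_test), prev) for name in candidate_names(config)}
    with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in config.lr_c_grid:
            lr = LogisticRegression(C=c, max_iter=1000)
            lr.fit(X_train, y_train)
            out[f"lr_C={c:g}"] = lr.predict_proba(X_test)[:, 1]
        n_max = max(config.gb_n_estimators)
        for d in config.gb_max_depths:
            gb = GradientBoostingClassifier(
                n_estimators=n_max,
                max_depth=d,
                learning_rate=config.gb_learning_rate,
                random_state=seed,
            )
            gb.fit(X_train, y_train)
            staged = list(gb.staged_predict_proba(X_test))
            for n in config.gb_n_estimators:
                out[f"gb_n={n}_d={d}"] = staged[min(n, len(staged)) - 1][:, 1]
    return out


def fit_single(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ModelConfig,
    seed: int,
) -> np.ndarray:
    """Test probabilities for one named candidate configuration."""
    prev = float(np.mean(y_train))
    if X_train.shape[1] == 0 or len(np.unique(y_train)) < 2:
        return np.full(len(X_test), prev)
    with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if name.startswith("lr_C="):
            lr = LogisticRegression(C=float(name.split("=")[1]), max_iter=1000)
            lr.fit(X_train, y_train)
            return lr.predict_proba(X_test)[:, 1]
        n = int(name.split("_")[1].split("=")[1])
        d = int(name.split("=")[-1])
        gb = GradientBoostingClassifier(
            n_estimators=n, max_depth=d,
            learning_rate=config.gb_learning_rate, random_state=seed,
        )
        gb.fit(X_train, y_train)
        return gb.predict_proba(X_test)[:, 1]


@dataclasses.dataclass
class SensorModel:
    """Winning 1-sensor model and its cross-validated probabilities.

    The winning configuration is chosen inside each training fold (inner
    validation split), so it may differ between folds.
    """

    sensor: str
    config_per_fold: dict[int, str]   # fold -> winning candidate name
    cv_f1: float                      # pooled out-of-fold F1
    oof_proba: pd.Series              # out-of-fold positive-class probability per participant
    train_meta: dict[int, pd.Series]  # fold -> inner-pass probabilities for that fold's training rows
    selected_per_fold: dict[int, list]


def stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Split indices into (fit, validation) keeping both classes in each part."""
    fit_idx, val_idx = [], []
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        k = min(max(1, int(round(fraction * len(members)))), len(members) - 1)
        fit_idx.append(members[:k])
        val_idx.append(members[k:])
    return np.sort(np.concatenate(fit_idx)), np.sort(np.concatenate(val_idx))


def choose_config(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    seed: int,
) -> str:
    """Pick the candidate configuration by F1 on an inner stratified
    validation split of the training rows (never sees test rows)."""
    from .evaluation import compute_metrics

    if X_train.shape[1] == 0 or len(np.unique(y_train)) < 2:
        return candidate_names(config)[0]
    fit_idx, val_idx = stratified_split(y_train, 0.75, rng)
    probs = fit_candidates(X_train[fit_idx], y_train[fit_idx], X_train[val_idx], config, seed)
    best_name, best_f1 = None, -1.0
    for name in candidate_names(config):
        f1 = compute_metrics(y_train[val_idx], (probs[name] >= 0.5).astype(int))["f1"]
        if f1 > best_f1:
            best_name, best_f1 = name, f1
    return best_name


def enumerate_combinations(sensors: Sequence[str] = SENSORS) -> list[tuple[str, ...]]:
    """All sensor subsets of size >= 2 in deterministic order (by size, then
    lexicographic): 57 for six sensors."""
    sensors = sorted(sensors)
    if len(sensors) < 2:
        raise ValueError("need at least 2 sensors to enumerate combinations")
    out: list[tuple[str, ...]] = []
    for k in range(2, len(sensors) + 1):
        out.extend(itertools.combinations(sensors, k))
    return out


def _make_ensemble(config: EnsembleConfig, seed: int) -> AdaBoostClassifier:
    base = GradientBoostingClassifier(
        n_estimators=config.base_n_estimators,
        max_depth=config.base_max_depth,
        learning_rate=config.base_learning_rate,
        random_state=seed,
    )
    return AdaBoostClassifier(
        estimator=base, n_estimators=max(config.n_estimators_grid), random_state=seed
    )


def staged_ensemble_proba(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: EnsembleConfig,
    seed: int,
) -> dict[int, np.ndarray]:
    """Fit one boosted ensemble and read test probabilities at every grid
    value of n_estimators from the staged prefix (boosting is sequential, so
    the g-stage prefix equals a fit with n_estimators=g)."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("ensemble training requires both classes")
    if X_train.shape[1] == 0 or np.all(X_train.std(axis=0) == 0):
        # uninformative meta-features: boosting cannot improve on prevalence
        prev = float(np.mean(y_train))
        return {g: np.full(len(X_test), prev) for g in config.n_estimators_grid}
    ada = _make_ensemble(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ada.fit(X_train, y_train)
        staged = list(ada.staged_predict_proba(X_test))
    return {g: staged[min(g, len(staged)) - 1][:, 1] for g in config.n_estimators_grid}


def tuned_ensemble_proba(
    meta_train: np.ndarray,
    y_train: np.ndarray,
    meta_test: np.ndarray,
    config: EnsembleConfig,
    seed: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Test probabilities of the boosted ensemble with n_estimators tuned on
    an inner stratified validation split of the training rows.

    When boosting terminates after a single stage (the base learner already
    fits the training data perfectly) every grid value yields the same model
    and tuning is skipped. Returns (test probabilities, chosen n_estimators).
    """
    from .evaluation import compute_metrics

    if len(np.unique(y_train)) < 2:
        raise ValueError("ensemble training requires both classes")
    if meta_train.shape[1] == 0 or np.all(meta_train.std(axis=0) == 0):
        prev = float(np.mean(y_train))
        return np.full(len(meta_test), prev), min(config.n_estimators_grid)
    ada = _make_ensemble(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ada.fit(meta_train, y_train)
        staged = list(ada.staged_predict_proba(meta_test))
    n_stages = len(staged)
    grid = sorted(config.n_estimators_grid)
    if n_stages == 1:
        return staged[0][:, 1], grid[0]
    fit_idx, val_idx = stratified_split(y_train, 0.75, rng)
    inner = staged_ensemble_proba(
        meta_train[fit_idx], y_train[fit_idx], meta_train[val_idx], config, seed
    )
    best_g, best_f1 = grid[0], -1.0
    for g in grid:
        f1 = compute_metrics(y_train[val_idx], (inner[g] >= 0.5).astype(int))["f1"]
        if f1 > best_f1:
            best_g, best_f1 = g, f1
    return staged[min(best_g, n_stages) - 1][:, 1], best_g


def train_ensemble(
    meta: pd.DataFrame,
    y: pd.Series,
    config: EnsembleConfig,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[AdaBoostClassifier, int, pd.Series]:
    """Train the late-fusion ensemble on a meta-feature matrix.

    ``meta`` holds positive-class detection probabilities (columns in
    canonical sensor order). n_estimators is chosen from the grid by
    leave-5-participants-out F1 when a fold plan is given (otherwise the
    smallest grid value). Returns the refit ensemble, the chosen
    n_estimators, and the cross-validated probabilities used for tuning.
    """
    from .evaluation import compute_metrics, make_folds

    if not ((meta.to_numpy() >= 0) & (meta.to_numpy() <= 1)).all():
        raise ValueError("meta-features must be probabilities in [0, 1]")
    yv = y.loc[meta.index].to_numpy()
    if folds is None:
        folds = make_folds(list(meta.index), seed=config.seed)
    oof = {g: pd.Series(np.nan, index=meta.index) for g in config.n_estimators_grid}
    for fi, (train_ids, test_ids) in enumerate(folds):
        probs = staged_ensemble_proba(
            meta.loc[train_ids].to_numpy(), y.loc[train_ids].to_numpy(),
            meta.loc[test_ids].to_numpy(), config, seed=config.seed + fi,
        )
        for g, pvec in probs.items():
            oof[g].loc[test_ids] = pvec
    best_g, best_f1 = None, -1.0
    for g in sorted(config.n_estimators_grid):
        f1 = compute_metrics(yv, (oof[g].to_numpy() >= 0.5).astype(int))["f1"]
        if f1 > best_f1:
            best_g, best_f1 = g, f1
    cfg = dataclasses.replace(config, n_estimators_grid=(best_g,))
    model = _make_ensemble(cfg, seed=config.seed)
    model.set_params(n_estimators=best_g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(meta.to_numpy(), yv)
    return model, best_g, oof[best_g]
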