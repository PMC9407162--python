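"""Cross-validation harness, metrics, and the end-to-end pipeline driver.

Validation is leave-5-participants-out: participants are permuted once under
the run seed and split into consecutive blocks of five (the last block may be
smaller); every participant is tested exactly once, and metrics are pooled
over folds into a single confusion matrix. The baseline is a majority
classifier refit on each training fold.

Fold discipline: feature selection, imputation statistics, and the stacking
inputs of the ensemble trained for a fold are computed from that fold's
training participants only; the harness records the participant sets used at
each step so the discipline can be audited.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import OUTCOMES, SENSORS
from .features import FeatureConfig, build_matrices, participant_daily, participant_deltas
from .ingest import CoverageThresholds, load_streams, valid_days_for_sensor
from .models import (
    EnsembleConfig,
    ModelConfig,
    SensorModel,
    choose_config,
    enumerate_combinations,
    fit_single,
    tuned_ensemble_proba,
)
from .outcomes import build_outcomes, outcome_correlations
from .selection import StabilityConfig, nested_select
from .synthetic import CohortConfig, iter_participants

logger = logging.getLogger("mssense")


# ---------------------------------------------------------------------------
# Folds, metrics, baseline
# ---------------------------------------------------------------------------

def make_folds(
    participant_ids: Sequence, seed: int, block_size: int = 5
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-``block_size``-participants-out fold plan.

    Deterministic under the seed: a seeded permutation split into consecutive
    blocks; the last block may be smaller. Returns (train_ids, test_ids)
    pairs covering every participant exactly once.
    """
    ids = np.asarray(list(participant_ids))
    if len(ids) <= block_size:
        raise ValueError(
            f"need more than {block_size} participants for leave-{block_size}-out folds"
        )
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = ids[perm]
    folds = []
    for start in range(0, len(ids), block_size):
        test = shuffled[start : start + block_size]
        train = np.concatenate([shuffled[:start], shuffled[start + block_size :]])
        folds.append((train, test))
    return folds


def make_stratified_folds(
    participant_ids: Sequence, labels: pd.Series, seed: int, block_size: int = 5
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified leave-~5-participants-out plan.

    Test blocks of about ``block_size`` participants with class proportions
    preserved, so the pooled majority baseline tracks the majority-class
    share instead of anticorrelating with the held-out blocks when
    prevalence sits near 0.5.
    """
    from sklearn.model_selection import StratifiedKFold

    ids = np.asarray(list(participant_ids))
    if len(ids) <= block_size:
        raise ValueError(
            f"need more than {block_size} participants for leave-{block_size}-out folds"
        )
    y = labels.loc[ids].to_numpy()
    n_splits = int(np.ceil(len(ids) / block_size))
    n_splits = min(n_splits, int(np.bincount(y.astype(int)).min())) or 2
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    return [(ids[tr], ids[te]) for tr, te in skf.split(ids, y)]


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, precision, recall and F1 for the positive class (the outcome
    of interest); precision/recall are 0 when undefined, and so is F1."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true) if len(y_true) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def majority_baseline(train_labels: np.ndarray, test_labels: np.ndarray) -> dict[str, float]:
    """Metrics of a constant classifier predicting the training majority
    class (ties go to the positive class)."""
    train_labels = np.asarray(train_labels).astype(int)
    if len(train_labels) == 0:
        raise ValueError("majority baseline needs non-empty training labels")
    majority = 1 if np.mean(train_labels) >= 0.5 else 0
    pred = np.full(len(test_labels), majority)
    return compute_metrics(test_labels, pred)


# ---------------------------------------------------------------------------
# Pipeline configuration and result containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration: either a cohort directory or a
    simulation config, plus all stage configurations."""

    cohort: CohortConfig | None = None
    data_dir: str | Path | None = None
    seed: int = 0
    outcomes: tuple[str, ...] = OUTCOMES
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    coverage: CoverageThresholds = dataclasses.field(default_factory=CoverageThresholds)
    stability: StabilityConfig = dataclasses.field(default_factory=StabilityConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    ensemble: EnsembleConfig = dataclasses.field(default_factory=EnsembleConfig)
    period_bounds: tuple[datetime.date, datetime.date, datetime.date] | None = None

    def resolve_periods(self) -> tuple[datetime.date, datetime.date, datetime.date]:
        if self.period_bounds is not None:
            return self.period_bounds
        if self.cohort is not None:
            return (self.cohort.study_start, self.cohort.period_boundary, self.cohort.study_end)
        raise ValueError("period_bounds must be given when loading a cohort directory")


@dataclasses.dataclass
class OutcomeResult:
    """ModelReports for one outcome."""

    outcome: str
    reports: pd.DataFrame        # one row per model (6 single + 57 combinations)
    best: pd.Series              # best combination's row
    baseline: dict[str, float]
    sensor_models: dict[str, SensorModel]
    fold_audit: list[dict]
    selection_report: pd.DataFrame


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    coverage_table: pd.DataFrame
    eligible: dict[str, bool]
    matrices: dict[str, pd.DataFrame]
    outcome_table: pd.DataFrame
    correlations: pd.DataFrame | None
    results: dict[str, OutcomeResult]


# ---------------------------------------------------------------------------
# Feature extraction over a cohort (streaming per participant)
# ---------------------------------------------------------------------------

def extract_cohort(
    participants: Iterable[tuple[str, Mapping[str, pd.DataFrame]]],
    period_bounds: tuple[datetime.date, datetime.date, datetime.date],
    thresholds: CoverageThresholds,
    fconfig: FeatureConfig,
) -> tuple[dict[str, dict[str, pd.Series]], dict[str, bool], pd.DataFrame]:
    """Coverage-check and featurize participants one at a time.

    Returns (behavior-change vectors per participant per sensor, eligibility
    flags, coverage table). Raw streams can be garbage-collected after each
    participant.
    """
    start, boundary, end = period_bounds
    deltas: dict[str, dict[str, pd.Series]] = {}
    eligible: dict[str, bool] = {}
    cov_rows = []
    for pid, streams in participants:
        vdays: dict[str, set] = {}
        usable: dict[str, bool] = {}
        for sensor in SENSORS:
            days = valid_days_for_sensor(streams, sensor, thresholds)
            days = {d for d in days if start <= d < end}
            vdays[sensor] = days
            pre = sum(1 for d in days if d < boundary)
            stay = len(days) - pre
            usable[sensor] = (
                pre >= thresholds.min_valid_days and stay >= thresholds.min_valid_days
            )
            cov_rows.append({"participant_id": pid, "sensor": sensor,
                             "pre_valid_days": pre, "stay_valid_days": stay,
                             "usable": usable[sensor]})
        eligible[pid] = any(usable.values())
        if not eligible[pid]:
            logger.info("participant %s ineligible (insufficient coverage)", pid)
            continue
        pdaily = participant_daily(streams, vdays, fconfig)
        deltas[pid] = participant_deltas(pdaily, period_bounds, usable, fconfig)
    return deltas, eligible, pd.DataFrame(cov_rows)


# ---------------------------------------------------------------------------
# Per-fold preprocessing
# ---------------------------------------------------------------------------

def _impute_standardize(
    X: pd.DataFrame, train_ids: np.ndarray
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Median-impute and z-score all rows using training-fold statistics
    only. All-missing training columns impute to 0 and scale by 1."""
    train = X.loc[train_ids]
    med = train.median(axis=0, skipna=True).fillna(0.0)
    filled = X.fillna(med)
    mean = filled.loc[train_ids].mean(axis=0)
    std = filled.loc[train_ids].std(axis=0, ddof=0).replace(0.0, 1.0)
    return (filled - mean) / std, med, mean, std


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# One outcome end to end
# ---------------------------------------------------------------------------

def run_outcome(
    outcome: str,
    matrices: Mapping[str, pd.DataFrame],
    labels: pd.Series,
    seed: int,
    stability: StabilityConfig,
    model_config: ModelConfig,
    ensemble_config: EnsembleConfig,
) -> OutcomeResult:
    """Nested selection, 1-sensor models, stacking and the 57-combination
    ablation for a single outcome under a shared leave-5-out fold plan."""
    pids = [p for p in matrices[SENSORS[0]].index if p in labels.index and pd.notna(labels[p])]
    y = labels.loc[pids].astype(int)
    folds = make_stratified_folds(pids, y, seed=_derive_seed(seed, 7))
    audit: list[dict] = []
    sel_reports = []

    sensor_models: dict[str, SensorModel] = {}
    for si, sensor in enumerate(SENSORS):
        X = matrices[sensor].loc[pids]
        oof = pd.Series(np.nan, index=pids)
        selected_per_fold: dict[int, list] = {}
        config_per_fold: dict[int, str] = {}
        train_meta: dict[int, pd.Series] = {}
        for fi, (tr, te) in enumerate(folds):
            ytr = y.loc[tr].to_numpy()
            Xs, med, mean, std = _impute_standardize(X, tr)
            scfg = dataclasses.replace(stability, seed=_derive_seed(seed, 1, si, fi))
            selected, rep = nested_select(Xs.loc[tr], ytr, scfg)
            selected_per_fold[fi] = selected
            rep["fold"] = fi
            rep["sensor"] = sensor
            sel_reports.append(rep)
            cols = list(selected)
            Xtr = Xs.loc[tr, cols].to_numpy()
            # hyperparameters chosen on an inner validation split of the
            # training rows only
            winner = choose_config(
                Xtr, ytr, model_config,
                rng=np.random.default_rng(_derive_seed(seed, 2, si, fi)),
                seed=_derive_seed(seed, 2, si, fi),
            )
            config_per_fold[fi] = winner
            oof.loc[te] = fit_single(
                winner, Xtr, ytr, Xs.loc[te, cols].to_numpy(), model_config,
                seed=_derive_seed(seed, 3, si, fi),
            )
            # inner leave-5-out pass -> leakage-free training meta-features
            # (leave-one-out when the training fold is very small)
            inner_block = 5 if len(tr) > 5 else 1
            inner = make_folds(tr, seed=_derive_seed(seed, 4, si, fi), block_size=inner_block)
            inner_oof = pd.Series(np.nan, index=tr)
            for ii, (itr, ite) in enumerate(inner):
                inner_oof.loc[ite] = fit_single(
                    winner, Xs.loc[itr, cols].to_numpy(), y.loc[itr].to_numpy(),
                    Xs.loc[ite, cols].to_numpy(), model_config,
                    seed=_derive_seed(seed, 5, si, fi, ii),
                )
            train_meta[fi] = inner_oof
            for step in ("selection", "imputation", "hyperparameters", "stacking"):
                audit.append({
                    "outcome": outcome, "sensor": sensor, "fold": fi, "step": step,
                    "rows_used": set(tr), "test_rows": set(te),
                })
        cv_f1 = compute_metrics(y.to_numpy(), (oof.to_numpy() >= 0.5).astype(int))["f1"]
        sensor_models[sensor] = SensorModel(
            sensor=sensor, config_per_fold=config_per_fold, cv_f1=cv_f1,
            oof_proba=oof.clip(0.0, 1.0),
            train_meta=train_meta, selected_per_fold=selected_per_fold,
        )

    # ---- baseline -----------------------------------------------------
    base_pred = pd.Series(0, index=pids)
    for tr, te in folds:
        maj = 1 if y.loc[tr].mean() >= 0.5 else 0
        base_pred.loc[te] = maj
    baseline = compute_metrics(y.to_numpy(), base_pred.to_numpy())

    # ---- ablation over sensor combinations ----------------------------
    rows = []
    for sensor in SENSORS:
        m = compute_metrics(
            y.to_numpy(), (sensor_models[sensor].oof_proba.to_numpy() >= 0.5).astype(int)
        )
        rows.append(_report_row(outcome, (sensor,), m, baseline))
    combos = enumerate_combinations(SENSORS)
    for ci, combo in enumerate(combos):
        combo_oof = pd.Series(np.nan, index=pids)
        chosen_g = []
        for fi, (tr, te) in enumerate(folds):
            meta_tr = pd.DataFrame(
                {s: sensor_models[s].train_meta[fi] for s in combo}
            ).clip(0.0, 1.0)
            meta_te = pd.DataFrame(
                {s: sensor_models[s].oof_proba.loc[te] for s in combo}
            ).clip(0.0, 1.0)
            probs, g = tuned_ensemble_proba(
                meta_tr.to_numpy(), y.loc[tr].to_numpy(), meta_te.to_numpy(),
                ensemble_config, seed=_derive_seed(seed, 6, ci, fi),
                rng=np.random.default_rng(_derive_seed(seed, 6, ci, fi)),
            )
            combo_oof.loc[te] = probs
            chosen_g.append(g)
        gm = compute_metrics(y.to_numpy(), (combo_oof.to_numpy() >= 0.5).astype(int))
        rows.append(
            _report_row(outcome, combo, gm, baseline,
                        n_estimators=int(np.median(chosen_g)))
        )
    reports = pd.DataFrame(rows)

    combo_rows = reports[reports["n_sensors"] >= 2].reset_index(drop=True)
    best_idx, best_key = 0, None
    for i, row in combo_rows.iterrows():
        key = (row["f1"], row["accuracy"], -row["n_sensors"])
        if best_key is None or key > best_key:
            best_idx, best_key = i, key
    best = combo_rows.loc[best_idx]
    sel_report = pd.concat(sel_reports, ignore_index=True) if sel_reports else pd.DataFrame()
    return OutcomeResult(
        outcome=outcome, reports=reports, best=best, baseline=baseline,
        sensor_models=sensor_models, fold_audit=audit, selection_report=sel_report,
    )


def _report_row(outcome, sensors, metrics, baseline, n_estimators=None) -> dict:
    improvement = (
        (metrics["accuracy"] - baseline["accuracy"]) / baseline["accuracy"] * 100.0
        if baseline["accuracy"] > 0 else np.nan
    )
    return {
        "outcome": outcome,
        "sensors": "+".join(sensors),
        "n_sensors": len(sensors),
        "accuracy": metrics["accuracy"],
        "precision": metrics["precision"],
        "recall": metrics["recall"],
        "f1": metrics["f1"],
        "baseline_accuracy": baseline["accuracy"],
        "improvement_pct": improvement,
        "n_estimators": n_estimators if n_estimators is not None else 0,
    }


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Ingest -> coverage -> features -> outcomes -> per-fold selection ->
    models -> ablation, for each requested outcome."""
    periods = config.resolve_periods()

    if config.data_dir is not None:
        streams, _ = load_streams(config.data_dir)
        questionnaires = pd.read_csv(Path(config.data_dir) / "questionnaires.csv")
        participants = iter(sorted(streams.items()))
    elif config.cohort is not None:
        from .synthetic import generate_questionnaires, make_profiles

        profiles = make_profiles(config.cohort)
        questionnaires = generate_questionnaires(profiles, config.cohort)
        participants = (
            (prof.participant_id, s)
            for prof, s in iter_participants(config.cohort, profiles)
        )
    else:
        raise ValueError("PipelineConfig needs either a cohort config or a data_dir")

    logger.info("extracting features (seed=%d)", config.seed)
    deltas, eligible, cov_table = extract_cohort(
        participants, periods, config.coverage, config.features
    )
    matrices = build_matrices(deltas, eligible)
    logger.info("eligible participants: %d / %d", sum(eligible.values()), len(eligible))

    outcome_table = build_outcomes(questionnaires, periods[1], periods[2])
    wide = outcome_table.pivot(index="participant_id", columns="outcome", values="average")
    try:
        correlations, _ = outcome_correlations(wide)
    except ValueError:
        correlations = None

    results: dict[str, OutcomeResult] = {}
    labels_wide = outcome_table.pivot(index="participant_id", columns="outcome", values="label")
    for outcome in config.outcomes:
        if outcome not in labels_wide.columns:
            continue
        logger.info("running outcome %s", outcome)
        results[outcome] = run_outcome(
            outcome, matrices, labels_wide[outcome].dropna(),
            seed=config.seed, stability=config.stability,
            model_config=config.model, ensemble_config=config.ensemble,
        )
    return PipelineResult(
        config=config, coverage_table=cov_table, eligible=eligible,
        matrices=matrices, outcome_table=outcome_table,
        correlations=correlations, results=results,
    )


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    """Write per-outcome model reports and run summaries as deterministic
    delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for outcome, res in result.results.items():
        res.reports.to_csv(out / f"report_{outcome}.csv", index=False, float_format="%.6f")
        res.selection_report.to_csv(
            out / f"selection_{outcome}.csv", index=False, float_format="%.6f"
        )
    result.coverage_table.to_csv(out / "coverage.csv", index=False, float_format="%.6f")
    result.outcome_table.to_csv(out / "outcomes.csv", index=False, float_format="%.6f")
    if result.correlations is not None:
        result.correlations.to_csv(out / "outcome_correlations.csv", float_format="%.6f")
    summary = pd.DataFrame(
        [
            {
                "outcome": o,
                "best_sensors": r.best["sensors"],
                "best_accuracy": r.best["accuracy"],
                "best_f1": r.best["f1"],
                "baseline_accuracy": r.baseline["accuracy"],
                "improvement_pct": r.best["improvement_pct"],
            }
            for o, r in result.results.items()
        ]
    )
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    # reproducibility metadata: every knob needed to regenerate the reports
    import json

    def as_dict(obj):
        return {k: str(v) for k, v in dataclasses.asdict(obj).items()} if obj else None

    meta = {
        "seed": result.config.seed,
        "outcomes": list(result.config.outcomes),
        "cohort": as_dict(result.config.cohort),
        "stability": as_dict(result.config.stability),
        "model": as_dict(result.config.model),
        "ensemble": as_dict(result.config.ensemble),
        "coverage": as_dict(result.config.coverage),
    }
    (out / "run_config.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
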