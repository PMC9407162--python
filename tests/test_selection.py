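"""Stability selection: recovery, null behavior, nesting, and the batched
proximal solver against the scikit-learn liblinear route."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mssense.features import feature_keys
from mssense.selection import (
    SelectionResult,
    StabilityConfig,
    nested_select,
    stability_select,
)


def _standardize(X):
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - X.mean(axis=0)) / std


class TestStabilitySelect:
    def test_strong_single_feature_always_selected(self):
        # one feature carrying y's margin plus tiny noise among 49 noise features
        rng = np.random.default_rng(0)
        y = (rng.random(100) < 0.5).astype(int)
        X = rng.normal(size=(100, 50))
        X[:, 0] = (2 * y - 1) + rng.normal(0, 0.1, 100)
        res = stability_select(pd.DataFrame(_standardize(X)), y, StabilityConfig(seed=0))
        assert res.frequency[0] >= 0.9
        assert 0 in res.selected

    def test_planted_selection_stable_noise_selection_unstable(self):
        """Stability is the statistic: reseeding the resampling leaves a
        planted signal's selected set nearly unchanged, while pure-noise
        selections barely overlap across reseedings."""

        def jaccard(a, b):
            a, b = set(a), set(b)
            return len(a & b) / len(a | b) if a | b else 1.0

        rng = np.random.default_rng(7)
        y = (rng.random(100) < 0.5).astype(int)
        noise = _standardize(rng.normal(size=(100, 50)))
        planted = noise.copy()
        planted[:, :5] += 1.5 * y[:, None]
        planted = _standardize(planted)
        noise_sets, planted_sets = [], []
        for seed in (0, 1, 2):
            cfg = StabilityConfig(seed=seed)
            noise_sets.append(stability_select(pd.DataFrame(noise), y, cfg).selected)
            planted_sets.append(
                [c for c in stability_select(pd.DataFrame(planted), y, cfg).selected]
            )
        planted_overlap = np.mean([jaccard(planted_sets[i], planted_sets[j])
                                   for i in range(3) for j in range(i + 1, 3)])
        noise_overlap = np.mean([jaccard(noise_sets[i], noise_sets[j])
                                 for i in range(3) for j in range(i + 1, 3)])
        assert planted_overlap >= 0.8
        assert all(set(range(5)) <= set(s) for s in planted_sets)
        assert noise_overlap < planted_overlap

    def test_zero_columns_give_empty_selection(self):
        X = pd.DataFrame(np.zeros((30, 4)))
        y = np.tile([0, 1], 15)
        res = stability_select(X, y, StabilityConfig(seed=0))
        assert res.selected == []
        assert (res.frequency == 0).all()

    def test_single_class_warns_and_selects_nothing(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.warns(UserWarning, match="single-class"):
            res = stability_select(X, np.ones(20, dtype=int), StabilityConfig(seed=0))
        assert res.selected == []

    def test_raising_threshold_never_enlarges_selection(self):
        rng = np.random.default_rng(3)
        y = (rng.random(80) < 0.5).astype(int)
        X = rng.normal(size=(80, 30))
        X[:, :3] += 1.2 * y[:, None]
        cfg = StabilityConfig(seed=5)
        freq = stability_select(pd.DataFrame(_standardize(X)), y, cfg).frequency
        previous = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            current = set(freq[freq >= thr].index)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        y = (rng.random(60) < 0.5).astype(int)
        X = pd.DataFrame(_standardize(rng.normal(size=(60, 20))))
        a = stability_select(X, y, StabilityConfig(seed=9))
        b = stability_select(X, y, StabilityConfig(seed=9))
        assert (a.frequency == b.frequency).all()

    def test_proximal_solver_agrees_with_liblinear(self):
        """The batched FISTA route and the per-fit scikit-learn route are two
        implementations of the same randomized-L1 statistic; their selection
        frequencies must agree closely under the same resamples."""
        rng = np.random.default_rng(6)
        y = (rng.random(90) < 0.5).astype(int)
        X = rng.normal(size=(90, 25))
        X[:, :4] += 1.5 * y[:, None]
        Xs = pd.DataFrame(_standardize(X))
        fast = stability_select(Xs, y, StabilityConfig(seed=2, solver="proximal"))
        slow = stability_select(Xs, y, StabilityConfig(seed=2, solver="liblinear"))
        assert np.abs(fast.frequency - slow.frequency).mean() < 0.05
        assert set(fast.frequency.nlargest(4).index) == set(slow.frequency.nlargest(4).index)


class TestNestedSelect:
    def _sensor_matrix(self, rng, n=80):
        cols = pd.MultiIndex.from_tuples(feature_keys("calls"),
                                         names=["sensor", "slice", "feature"])
        X = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        return X

    def test_planted_groups_dominate_final_set(self):
        rng = np.random.default_rng(0)
        X = self._sensor_matrix(rng)
        y = (rng.random(len(X)) < 0.5).astype(int)
        informative_slices = {"night.weekdays", "evening.weekends"}
        for sl in informative_slices:
            X.loc[:, ("calls", sl, "n_incoming")] += 2.0 * y
            X.loc[:, ("calls", sl, "n_missed")] += 1.5 * y
        Xs = (X - X.mean()) / X.std()
        selected, report = nested_select(Xs, y, StabilityConfig(seed=1))
        assert selected
        # the planted slices contribute the highest-frequency survivors; the
        # permissive threshold may admit others at the margin
        from_planted = [col for col in selected if col[1] in informative_slices]
        assert any(col[2] == "n_incoming" for col in from_planted)
        glob = report[report["stage"] == "global"].set_index(["sensor", "slice", "feature"])
        top = glob["frequency"].nlargest(4).index
        assert all(col[1] in informative_slices for col in top)
        assert set(report["stage"]) == {"group", "global"}

    def test_all_noise_may_be_empty_and_never_crashes(self):
        rng = np.random.default_rng(1)
        X = self._sensor_matrix(rng, n=60)
        y = (rng.random(len(X)) < 0.5).astype(int)
        Xs = (X - X.mean()) / X.std()
        selected, report = nested_select(Xs, y, StabilityConfig(seed=2))
        assert isinstance(selected, list)

    def test_single_class_gives_empty_final_set(self):
        rng = np.random.default_rng(2)
        X = self._sensor_matrix(rng, n=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, _ = nested_select(X, np.ones(30, dtype=int), StabilityConfig(seed=0))
        assert selected == []

    def test_minimal_threshold_keeps_any_ever_selected(self):
        """At pi = 1/n_resamples, stage 1 keeps every feature that was ever
        selected, and the final set is a one-stage selection on that
        superset."""
        rng = np.random.default_rng(3)
        X = self._sensor_matrix(rng, n=60)
        y = (rng.random(len(X)) < 0.5).astype(int)
        Xs = (X - X.mean()) / X.std()
        cfg = StabilityConfig(seed=4, n_resamples=20, threshold=1 / 20)
        selected, report = nested_select(Xs, y, cfg)
        grp = report[report["stage"] == "group"]
        assert ((grp["frequency"] > 0) == grp["selected"]).all()
        survivors = [
            tuple(r[["sensor", "slice", "feature"]]) for _, r in grp.iterrows() if r["selected"]
        ]
        rng2 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        direct = stability_select(Xs[survivors], y, cfg, rng2, stage="global")
        assert set(selected) == set(direct.selected)

    def test_plain_columns_rejected(self):
        X = pd.DataFrame(np.zeros((20, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="MultiIndex"):
            nested_select(X, np.zeros(20, dtype=int), StabilityConfig(seed=0))
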