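"""Splits, SMOTE, classifier training/evaluation, feature importance."""

import numpy as np
import pandas as pd
import pytest

from sbdecode.decoding import (
    DEFAULT_GRIDS,
    SMOTESampler,
    StateDecoder,
    across_participant_split,
    feature_importance,
    fit_and_evaluate,
    smote_balance,
    within_participant_split,
)
from sbdecode.protocol import REST, SB_MINUS
from sbdecode.stats import binomial_vs_chance, univariate_threshold_accuracy


def blob_table(
    n_rows: int = 100,
    n_features: int = 5,
    effect: np.ndarray | None = None,
    n_participants: int = 1,
    participant_sd: float = 0.0,
    seed: int = 0,
    block: int = 5,
) -> pd.DataFrame:
    """Gaussian feature table with states alternating in chronological
    blocks, optionally shifting SB− rows by ``effect`` per feature."""
    rng = np.random.default_rng(seed)
    if effect is None:
        effect = np.zeros(n_features)
    frames = []
    for p in range(n_participants):
        X = rng.standard_normal((n_rows, n_features))
        X += participant_sd * rng.standard_normal(n_features)
        states = np.where((np.arange(n_rows) // block) % 2 == 0, REST, SB_MINUS)
        X[states == SB_MINUS] += effect
        frames.append(
            pd.DataFrame(
                {"participant": f"P{p:02d}", "state": states,
                 "epoch_idx": np.arange(n_rows),
                 **{f"feat__f{j}": X[:, j] for j in range(n_features)}}
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestWithinSplit:
    def test_100_row_percent_layout(self):
        plan = within_participant_split(blob_table(100))
        assert set(plan.eval_indices) == set(range(40, 50)) | set(range(90, 100))
        assert set(plan.removed_indices) == {39, 50, 89}
        assert set(plan.train_indices) == (
            set(range(0, 39)) | set(range(51, 89))
        )

    def test_eval_fraction_near_20_percent(self):
        plan = within_participant_split(blob_table(100))
        total = (
            len(plan.eval_indices) + len(plan.train_indices) + len(plan.removed_indices)
        )
        assert len(plan.eval_indices) / total == pytest.approx(0.20, abs=0.02)

    def test_no_eval_row_adjacent_to_train_row(self):
        for n in (60, 100, 137):
            plan = within_participant_split(blob_table(n))
            diffs = np.abs(
                plan.eval_indices[:, np.newaxis] - plan.train_indices[np.newaxis, :]
            )
            assert diffs.min() > 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            within_participant_split(blob_table(15))

    def test_multiple_participants_rejected(self):
        with pytest.raises(ValueError):
            within_participant_split(blob_table(100, n_participants=2))


class TestAcrossSplit:
    def test_41_participants_round_half_up(self):
        table = blob_table(4, n_participants=41)
        plan = across_participant_split(table, train_fraction=0.8, seed=1)
        train_p = set(table.iloc[plan.train_indices]["participant"])
        eval_p = set(table.iloc[plan.eval_indices]["participant"])
        assert len(train_p) == 33 and len(eval_p) == 8
        assert not train_p & eval_p

    def test_two_participants_split_one_and_one(self):
        table = blob_table(4, n_participants=2)
        plan = across_participant_split(table, seed=0)
        assert len(set(table.iloc[plan.train_indices]["participant"])) == 1
        assert len(set(table.iloc[plan.eval_indices]["participant"])) == 1

    def test_seed_determinism(self):
        table = blob_table(4, n_participants=10)
        a = across_participant_split(table, seed=7)
        b = across_participant_split(table, seed=7)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            across_participant_split(blob_table(10, n_participants=1))


class TestSmote:
    def test_balanced_input_is_identity(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat(["a", "b"], 10)
        X2, y2 = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(y, y2)

    def test_minor_imbalance_equalized(self, rng):
        X = rng.normal(size=(198, 4))
        y = np.array(["a"] * 100 + ["b"] * 98)
        X2, y2 = smote_balance(X, y, seed=0)
        _, counts = np.unique(y2, return_counts=True)
        assert counts.tolist() == [100, 100]
        # original rows come first, untouched
        np.testing.assert_array_equal(X2[:198], X)

    def test_synthetic_rows_lie_between_minority_pairs(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array(["maj"] * 30 + ["min"] * 10)
        X2, y2 = smote_balance(X, y, seed=3)
        minority = X[30:]
        for s in X2[40:]:
            found = False
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    r = s - minority[i]
                    cross = d[0] * r[1] - d[1] * r[0]
                    t = np.dot(r, d) / np.dot(d, d)
                    if abs(cross) < 1e-9 and -1e-12 <= t <= 1 + 1e-12:
                        found = True
            assert found, "synthetic row not on any minority segment"

    def test_small_minority_reduces_k_with_warning(self, rng):
        X = rng.normal(size=(24, 2))
        y = np.array(["a"] * 20 + ["b"] * 4)
        with pytest.warns(UserWarning, match="k_neighbors"):
            _, y2 = SMOTESampler(k_neighbors=5, random_state=0).fit_resample(X, y)
        assert (y2 == "b").sum() == 20

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            smote_balance(rng.normal(size=(10, 2)), np.array(["a"] * 10))


class TestStateDecoder:
    @pytest.mark.parametrize("family", ["lr", "svc", "rf", "gnb"])
    def test_separable_clouds_reach_perfect_accuracy(self, family, rng):
        X = rng.standard_normal((120, 4))
        y = np.repeat([REST, SB_MINUS], 60)
        X[y == SB_MINUS, 0] += 10.0  # ten SDs apart
        dec = StateDecoder(family=family, random_state=0).fit(X[:80], y[:80])
        assert dec.score(X[80:], y[80:]) == 1.0

    def test_tiny_c_shrinks_all_coefficients_to_zero(self, rng):
        X = rng.standard_normal((100, 6))
        y = np.repeat([REST, SB_MINUS], 50)
        X[y == SB_MINUS, 0] += 1.0
        dec = StateDecoder(family="lr", hyper_grid={"C": [1e-6]}, random_state=0)
        dec.fit(X, y)
        assert np.all(dec.coef_ == 0.0)
        assert abs(dec.score(X, y) - 0.5) < 1e-12

    def test_shuffled_labels_stay_at_chance(self, rng):
        """Permutation null: grid-searched LR on label-shuffled data scores
        within the 95% binomial band around 0.5."""
        accs = []
        n_eval = 60
        for _ in range(10):
            X = rng.standard_normal((200, 5))
            y = rng.permutation(np.repeat([REST, SB_MINUS], 100))
            dec = StateDecoder(family="lr", random_state=1).fit(
                X[:-n_eval], y[:-n_eval]
            )
            accs.append(dec.score(X[-n_eval:], y[-n_eval:]))
        total_n = 10 * n_eval
        half_width = 1.96 * np.sqrt(0.25 / total_n)
        assert abs(np.mean(accs) - 0.5) < half_width + 0.02

    def test_grid_tie_break_prefers_first_candidate(self, rng):
        X = rng.standard_normal((80, 3))
        y = np.repeat([REST, SB_MINUS], 40)
        X[y == SB_MINUS] += 8.0  # wide separation: these C values all tie
        dec = StateDecoder(
            family="lr", hyper_grid={"C": [1.0, 10.0, 100.0]}, random_state=0
        ).fit(X, y)
        assert dec.best_params_["C"] == 1.0  # simplest candidate wins the tie


class TestFitAndEvaluate:
    def test_planted_effect_decodes_and_balances_eval(self):
        table = blob_table(200, effect=np.array([6.0, 0, 0, 0, 0]), seed=4)
        plan = within_participant_split(table)
        res = fit_and_evaluate(plan, table, (SB_MINUS, REST),
                               feature_prefix="feat", seed=0)
        assert res.accuracy > 0.95
        counts = res.predictions["true"].value_counts()
        assert counts[REST] == counts[SB_MINUS]  # eval-side SMOTE balanced

    def test_multivariate_dominates_best_univariate(self):
        effect = np.full(8, 0.5)
        table = blob_table(400, n_features=8, effect=effect, seed=9)
        plan = within_participant_split(table)
        res = fit_and_evaluate(plan, table, (SB_MINUS, REST),
                               feature_prefix="feat", seed=0)
        best_uni = max(
            univariate_threshold_accuracy(
                table.loc[table.state == SB_MINUS, c],
                table.loc[table.state == REST, c],
                "high_is_positive",
            )
            for c in table.columns if c.startswith("feat__")
        )
        assert res.accuracy >= best_uni - 0.02

    def test_missing_contrast_state_rejected(self):
        table = blob_table(100)
        table["state"] = REST
        plan = within_participant_split(table)
        with pytest.raises(ValueError, match="missing contrast"):
            fit_and_evaluate(plan, table, (SB_MINUS, REST), feature_prefix="feat")


class TestFeatureImportance:
    def _result(self, effect, seed=0):
        table = blob_table(300, n_features=6, effect=effect, seed=seed)
        plan = within_participant_split(table)
        return fit_and_evaluate(plan, table, (SB_MINUS, REST),
                                feature_prefix="feat", seed=0)

    def test_single_planted_region_ranks_first(self):
        res = self._result(np.array([0, 0, 1.5, 0, 0, 0.0]))
        ranked = feature_importance(res)
        assert ranked.iloc[0]["feature"] == "feat__f2"
        assert ranked.iloc[0]["coefficient"] != 0

    def test_opposite_effects_get_opposite_signs(self):
        res = self._result(np.array([1.5, -1.5, 0, 0, 0, 0.0]))
        ranked = feature_importance(res).set_index("feature")["coefficient"]
        assert ranked["feat__f0"] * ranked["feat__f1"] < 0

    def test_non_lr_family_rejected(self):
        table = blob_table(100, effect=np.array([2.0, 0, 0, 0, 0]))
        plan = within_participant_split(table)
        res = fit_and_evaluate(plan, table, (SB_MINUS, REST),
                               family="gnb", feature_prefix="feat", seed=0)
        with pytest.raises(ValueError, match="lr"):
            feature_importance(res)
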