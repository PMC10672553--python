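import math

import numpy as np
import pandas as pd
import pytest

from marrowtex.errors import ParameterError, ValidationError
from marrowtex.feature_names import ALL_FEATURES
from marrowtex.model_pipeline import (
    balance_training_set,
    enumerate_combinations,
    evaluate_combination,
    rank_importance,
    repeat_evaluation,
    select_composite,
    to_wide,
)


def synthetic_feature_table(
    n_per_group=(24, 22, 26),
    signal_columns=(),
    shift=2.0,
    seed=0,
):
    """A cohort feature table of pure noise, with optional per-group shifts
    planted into ``signal_columns`` ("sequence:feature" specs)."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n in zip(("BME", "INJ", "OST"), n_per_group):
        for _ in range(n):
            for seq in ("PDFSE", "STIR"):
                row = {"subject_id": f"s{sid:03d}", "group": group, "sequence": seq}
                for feat in ALL_FEATURES:
                    value = rng.normal()
                    if f"{seq}:{feat}" in signal_columns:
                        value += shift * {"BME": 1, "INJ": 0, "OST": -1}[group]
                    row[feat] = value
                rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


PLANTED = (
    "PDFSE:glcm_joint_max",
    "PDFSE:glrlm_lrlge",
    "STIR:fo_mad",
    "STIR:glszm_glzv",
    "PDFSE:glrlm_rlv",
)


@pytest.fixture(scope="module")
def signal_table():
    return synthetic_feature_table(signal_columns=PLANTED, shift=1.5, seed=1)


@pytest.fixture(scope="module")
def noise_table():
    return synthetic_feature_table(seed=2)


class TestToWide:
    def test_joins_both_sequences(self, signal_table):
        X, y = to_wide(signal_table)
        assert X.shape == (72, 162)
        assert set(y) == {"BME", "INJ", "OST"}

    def test_missing_sequence_rejected(self, signal_table):
        broken = signal_table[
            ~((signal_table.subject_id == "s000") & (signal_table.sequence == "STIR"))
        ]
        with pytest.raises(ValidationError):
            to_wide(broken)


class TestRankImportance:
    def test_output_is_permutation(self, noise_table):
        ranked = rank_importance(noise_table, seed=0)
        X, _ = to_wide(noise_table)
        assert sorted(ranked) == sorted(X.columns)

    def test_recovers_planted_signal(self, signal_table):
        for seed in range(3):
            ranked = rank_importance(signal_table, seed=seed)
            top20 = set(ranked[:20])
            assert set(PLANTED) <= top20

    def test_deterministic(self, signal_table):
        assert rank_importance(signal_table, 7) == rank_importance(signal_table, 7)


class TestEnumerateCombinations:
    def test_binomial_sum_20_5(self):
        top = [f"f{i}" for i in range(25)]
        combos = enumerate_combinations(top, k_top=20, max_size=5)
        expected = sum(math.comb(20, k) for k in range(1, 6))
        assert len(combos) == expected == 21699

    def test_three_choose_up_to_two(self):
        combos = enumerate_combinations(["a", "b", "c"], k_top=3, max_size=2)
        assert len(combos) == 6

    def test_unique_and_bounded(self):
        combos = enumerate_combinations([f"f{i}" for i in range(8)], k_top=8, max_size=5)
        assert len(set(combos)) == len(combos)
        assert all(1 <= len(c) <= 5 for c in combos)

    def test_k_top_too_large(self):
        with pytest.raises(ParameterError):
            enumerate_combinations(["a"], k_top=2)


class TestBalance:
    def test_equalizes_after_factor_two(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(121, 4))
        y = np.repeat(["BME", "INJ", "OST"], [41, 37, 43])
        Xb, yb, prov = balance_training_set(X, y, seed=0, factor=2)
        counts = pd.Series(yb).value_counts()
        assert set(counts) == {86}
        assert len(prov) == len(yb)

    def test_balanced_factor_one_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = np.repeat(["BME", "INJ", "OST"], 10)
        Xb, yb, prov = balance_training_set(X, y, seed=0, factor=1)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)
        assert all(len(t) == 1 for t in prov)

    def test_synthetic_rows_are_convex_combinations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.array(["BME"] * 25 + ["INJ"] * 10 + ["OST"] * 5)
        Xb, yb, prov = balance_training_set(X, y, seed=3, factor=1)
        for row, tag in zip(Xb, prov):
            if len(tag) == 1:
                np.testing.assert_allclose(row, X[tag[0]])
            else:
                a, b = X[tag[0]], X[tag[1]]
                d = b - a
                denom = np.where(np.abs(d) > 1e-12, d, np.nan)
                lam = (row - a) / denom
                lam = lam[np.isfinite(lam)]
                assert lam.size > 0
                np.testing.assert_allclose(lam, lam[0], atol=1e-9)
                assert -1e-9 <= lam[0] <= 1 + 1e-9

    def test_tiny_class_falls_back(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 2))
        y = np.array(["BME"] * 18 + ["INJ"] * 3 + ["OST"] * 3)
        Xb, yb, _ = balance_training_set(X, y, seed=0, factor=1)
        counts = pd.Series(yb).value_counts()
        assert set(counts) == {18}


class TestEvaluateCombination:
    def test_separable_classes_are_perfect(self, signal_table):
        result = evaluate_combination(
            synthetic_feature_table(signal_columns=PLANTED, shift=25.0, seed=5),
            PLANTED,
            seed=0,
            fast=True,
        )
        assert result["acc"] == 1.0
        assert result["auc"] == 1.0
        for g in ("bme", "inj", "ost"):
            assert result[f"tpr_{g}"] == 1.0

    def test_no_test_row_in_training_provenance(self, signal_table):
        result = evaluate_combination(signal_table, PLANTED[:3], seed=1, fast=True)
        train_sources = {i for tag in result["train_provenance"] for i in tag}
        assert train_sources.isdisjoint(result["test_rows"])
        assert train_sources <= set(result["train_rows"])

    def test_paper_order_leaks(self, signal_table):
        result = evaluate_combination(
            signal_table, PLANTED[:3], seed=1, fast=True, paper_order=True
        )
        train_sources = {i for tag in result["train_provenance"] for i in tag}
        assert not train_sources.isdisjoint(result["test_rows"])

    def test_unknown_feature_rejected(self, signal_table):
        with pytest.raises(ValidationError):
            evaluate_combination(signal_table, ("PDFSE:nope",), seed=0, fast=True)

    def test_grid_search_path(self, signal_table):
        result = evaluate_combination(
            signal_table, PLANTED[:2], seed=0, fast=False, cv_folds=3,
            tree_grid=(50, 100), depth_grid=(None, 5),
        )
        assert 0.0 <= result["acc"] <= 1.0
        assert 0.0 <= result["auc"] <= 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(6)
        accs = []
        for seed in range(8):
            table = synthetic_feature_table(seed=100 + seed)
            result = evaluate_combination(table, PLANTED, seed=seed, fast=True)
            accs.append(result["acc"])
        assert abs(np.mean(accs) - 1 / 3) < 0.12


class TestRepeatEvaluation:
    def test_report_structure(self, signal_table):
        report = repeat_evaluation(signal_table, PLANTED, base_seed=0, n_rep=3, fast=True)
        assert len(report.per_rep) == 3
        frame = report.to_frame()
        assert len(frame) == 4  # 3 repetitions + aggregate row
        for metric in report.METRICS:
            assert report.mean[metric] == pytest.approx(
                report.per_rep[metric].mean(), abs=1e-12
            )
            assert 0.0 <= report.mean[metric] <= 1.0


class TestSelectComposite:
    def test_single_informative_feature(self):
        table = synthetic_feature_table(
            signal_columns=("STIR:fo_mad",), shift=8.0, seed=9
        )
        composite, report = select_composite(
            table, base_seed=0, n_rep=3, k_top=6, max_size=2, budget=15
        )
        assert composite == ("STIR:fo_mad",)
        assert report.mean["auc"] > 0.9

    def test_deterministic(self):
        table = synthetic_feature_table(
            signal_columns=PLANTED[:2], shift=3.0, seed=10
        )
        a = select_composite(table, base_seed=3, n_rep=2, k_top=5, max_size=2, budget=10)
        b = select_composite(table, base_seed=3, n_rep=2, k_top=5, max_size=2, budget=10)
        assert a[0] == b[0]
        assert a[1].per_rep.equals(b[1].per_rep)

    def test_recovers_planted_in_ideal_world(self):
        # independent-noise nulls: the planted columns are the only signal;
        # moderate shift so every planted feature adds measurable AUC.
        # Majority voting over noisy per-repetition winners is unstable at
        # desk scale even here, so the bar is a majority of the planted set.
        table = synthetic_feature_table(signal_columns=PLANTED, shift=1.2, seed=11)
        composite, _ = select_composite(
            table, base_seed=0, n_rep=5, k_top=8, max_size=5, budget=200
        )
        assert len(set(composite) & set(PLANTED)) >= 3
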