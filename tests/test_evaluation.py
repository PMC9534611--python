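import numpy as np
import pandas as pd
import pytest

import oracles
from wavemics import (
    CLASSIFIER_FAMILIES,
    delong_test,
    evaluate_grid,
    make_classifier,
    percent_increase,
    repeated_cv,
    select_best,
)
from wavemics.evaluation import EvalGrid, comparison_rows


def separable_data(rng, n=60, sep=8.0):
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    X = rng.normal(size=(n, 4))
    X[y == 1, 0] += sep
    return X, y


class TestRepeatedCV:
    def test_separable_data_perfect_auc(self, rng):
        X, y = separable_data(rng)
        res = repeated_cv(X, y, "LR", folds=5, repeats=3, seed=0)
        assert res.mean_auc == pytest.approx(1.0)
        assert res.mean_accuracy >= 0.99

    def test_permuted_labels_auc_near_half(self, rng):
        X, y = separable_data(rng, n=80)
        y_perm = rng.permutation(y)
        res = repeated_cv(X, y_perm, "LR", folds=5, repeats=20, seed=1)
        assert res.mean_auc == pytest.approx(0.5, abs=0.08)

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = separable_data(rng, n=40, sep=1.0)
        r1 = repeated_cv(X, y, "RF", folds=5, repeats=2, seed=7)
        r2 = repeated_cv(X, y, "RF", folds=5, repeats=2, seed=7)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        np.testing.assert_array_equal(r1.pooled_scores, r2.pooled_scores)

    def test_record_count_is_repeats_times_folds(self, rng):
        X, y = separable_data(rng, n=40, sep=1.0)
        res = repeated_cv(X, y, "NB", folds=5, repeats=3, seed=0)
        assert len(res.records) == 15
        assert res.records[["accuracy", "auc", "f1"]].to_numpy().min() >= 0.0
        assert res.records[["accuracy", "auc", "f1"]].to_numpy().max() <= 1.0

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0] * 6 + [1] * 2)
        with pytest.raises(ValueError):
            repeated_cv(X, y, "LR", folds=5, repeats=1, seed=0)

    def test_every_family_constructs(self):
        for fam in CLASSIFIER_FAMILIES:
            assert make_classifier(fam) is not None
        with pytest.raises(ValueError):
            make_classifier("XGB")


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        y = np.array([0, 1] * 15)
        s = rng.normal(size=30)
        assert delong_test(s, s, y) == 1.0

    def test_internal_auc_matches_mann_whitney(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        from scipy.stats import mannwhitneyu

        pos, neg = s[y == 1], s[y != 1]
        u = mannwhitneyu(pos, neg).statistic / (len(pos) * len(neg))
        assert oracles.auc_mann_whitney(s, y) == pytest.approx(u, abs=1e-12)

    def test_agrees_with_permutation_oracle(self, rng):
        # n=40 synthetic scores with a modest real difference
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        latent = y + rng.normal(scale=1.2, size=n)
        s1 = latent + rng.normal(scale=0.4, size=n)
        s2 = 0.8 * latent + rng.normal(scale=0.9, size=n)
        p_delong = delong_test(s1, s2, y)
        p_perm = oracles.paired_permutation_auc_test(s1, s2, y, n_perm=3000, seed=0)
        assert p_delong == pytest.approx(p_perm, abs=0.07)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.normal(size=5), rng.normal(size=5), np.ones(5))


class TestGridAndComparison:
    def _make_grid(self, rng, n_banks=2, families=("LR", "NB")):
        X, y = separable_data(rng, n=40, sep=1.2)
        plain = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        profiles = {
            f"bank{i}": pd.DataFrame(rng.normal(size=(40, 6)) + y[:, None] * (0.5 + i),
                                     columns=[f"w{j}" for j in range(6)])
            for i in range(n_banks)
        }
        grid = evaluate_grid(plain, profiles, y, families, folds=5, repeats=2, seed=0)
        return grid, y

    def test_cell_counts(self, rng):
        grid, _ = self._make_grid(rng)
        assert grid.n_wavelet_cells() == 4
        assert len(grid.cells) == 6  # + plain row
        assert grid.metric_table("auc").shape == (2, 2)
        assert grid.plain_table().shape == (2, 3)

    def test_misaligned_rows_rejected(self, rng):
        X, y = separable_data(rng, n=40)
        plain = pd.DataFrame(X)
        with pytest.raises(ValueError):
            evaluate_grid(plain, {}, y[:-1], ("LR",), folds=5, repeats=1, seed=0)

    def test_select_best_prefers_dominant_cell(self, rng):
        grid, _ = self._make_grid(rng, n_banks=3)
        # bank2 has the strongest planted signal
        bank, fam = select_best(grid)
        assert bank == "bank2"

    def test_select_best_tie_breaks_lexicographically(self):
        grid = EvalGrid()
        rec = pd.DataFrame({"repeat": [0], "fold": [0],
                            "accuracy": [0.9], "auc": [0.9], "f1": [0.9]})
        from wavemics.evaluation import EvalResult

        for bank in ("zz", "aa"):
            grid.cells[(bank, "LR")] = EvalResult(rec, np.zeros(4), np.array([0, 0, 1, 1]))
        assert select_best(grid) == ("aa", "LR")

    def test_comparison_rows_structure(self, rng):
        grid, _ = self._make_grid(rng)
        rows = comparison_rows(grid, "auc")
        assert set(rows.index) == {"LR", "NB"}
        for fam in rows.index:
            expected = percent_increase(rows.loc[fam, "wavelet"], rows.loc[fam, "plain"])
            assert rows.loc[fam, "pct_increase"] == expected
            assert 0.0 <= rows.loc[fam, "p_value"] <= 1.0


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "wavelet,plain,expected",
        [(0.99, 0.88, 12.5), (0.96, 0.55, 74.5), (0.7, 0.7, 0.0)],
    )
    def test_values(self, wavelet, plain, expected):
        assert percent_increase(wavelet, plain) == expected

    def test_zero_plain_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(0.9, 0.0)
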