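"""Grouped stratified folds, box-constraint tuning, and CV evaluation."""

import numpy as np
import pandas as pd
import pytest

from phonoscope.classify import (
    SVMConfig,
    crossval_evaluate,
    make_grouped_stratified_folds,
    optimize_box_constraint,
    positive_class,
    repeat_pipeline,
)
from phonoscope.synth import synth_feature_table


def _pair_table(effect=1.0, n=20, rho=0.3, seed=0, k_informative=5):
    vec = np.zeros(38)
    vec[:k_informative] = effect
    return synth_feature_table(
        n, {"HC": np.zeros(38), "MDD": vec}, within_participant_rho=rho, seed=seed
    )


class TestFolds:
    def test_twenty_per_class_gives_balanced_folds(self):
        table = _pair_table()
        folds = make_grouped_stratified_folds(table, k=5, seed=1)
        for f in range(5):
            rows = table.iloc[folds.val_rows(f)]
            assert len(rows) == 32
            assert rows["participant_id"].nunique() == 8
            assert (rows.groupby("group")["participant_id"].nunique() == 4).all()

    def test_same_seed_reproduces_assignment(self):
        table = _pair_table()
        f1 = make_grouped_stratified_folds(table, k=5, seed=7)
        f2 = make_grouped_stratified_folds(table, k=5, seed=7)
        np.testing.assert_array_equal(f1.fold_of_row, f2.fold_of_row)

    @pytest.mark.parametrize("seed", range(25))
    def test_no_participant_ever_splits_across_folds(self, seed):
        table = _pair_table(seed=seed)
        folds = make_grouped_stratified_folds(table, k=5, seed=seed)
        per_pid = pd.Series(folds.fold_of_row).groupby(table["participant_id"]).nunique()
        assert (per_pid == 1).all()

    def test_too_few_participants_raises(self):
        table = _pair_table(n=3)
        with pytest.raises(ValueError, match="fewer than"):
            make_grouped_stratified_folds(table, k=5)


class TestBoxConstraint:
    def _toy(self):
        # linearly separable: one feature fully determines the class
        table = _pair_table(effect=6.0, n=10, rho=0.0, k_informative=38)
        x = table.iloc[:, 3:].to_numpy(float)
        y = table["group"].to_numpy()
        pids = table["participant_id"].to_numpy()
        return x, y, pids

    def test_separable_data_trains_perfectly_at_selected_c(self):
        from sklearn.svm import SVC

        x, y, pids = self._toy()
        cfg = SVMConfig(kernel_degree=1, optimizer="grid")
        c = optimize_box_constraint(x, y, pids, cfg, seed=0)
        model = SVC(kernel="linear", C=c).fit(x, y)
        assert (model.predict(x) == y).mean() == 1.0

    def test_fixed_seed_is_deterministic(self):
        x, y, pids = self._toy()
        cfg = SVMConfig(kernel_degree=1, optimizer="bayes", bayes_iterations=10)
        c1 = optimize_box_constraint(x, y, pids, cfg, seed=3)
        c2 = optimize_box_constraint(x, y, pids, cfg, seed=3)
        assert c1 == c2

    def test_bayes_and_grid_agree_within_one_grid_step(self):
        # oracle: exhaustive grid evaluation of the same inner-CV objective
        x, y, pids = self._toy()
        c_grid = optimize_box_constraint(
            x, y, pids, SVMConfig(kernel_degree=1, optimizer="grid"), seed=0
        )
        c_bayes = optimize_box_constraint(
            x, y, pids,
            SVMConfig(kernel_degree=1, optimizer="bayes", bayes_iterations=15),
            seed=0,
        )
        step = 6.0 / 12  # log10 spacing of the 13-point grid
        assert abs(np.log10(c_bayes) - np.log10(c_grid)) <= step + 1e-9


class TestCrossval:
    def test_strongly_separated_cohort_is_nearly_perfectly_classified(self):
        # 5 features shifted 2.2 SD -> Mahalanobis distance 4.9 between the
        # generating Gaussians; Bayes error well under 1%
        table = _pair_table(effect=2.2, rho=0.2, seed=4)
        folds = make_grouped_stratified_folds(table, k=5, seed=4)
        cfg = SVMConfig(kernel_degree=1, box_constraint=1.0)
        m = crossval_evaluate(table, folds, cfg)
        assert m.accuracy >= 0.95

    def test_permuted_labels_score_at_chance(self):
        accs = []
        for seed in range(12):
            table = _pair_table(effect=2.2, rho=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(table["participant_id"].nunique())
            pid_order = sorted(table["participant_id"].unique())
            new_group = {
                pid: ("HC" if i < len(pid_order) // 2 else "MDD")
                for pid, i in zip(pid_order, perm)
            }
            table["group"] = table["participant_id"].map(new_group)
            folds = make_grouped_stratified_folds(table, k=5, seed=seed)
            m = crossval_evaluate(table, folds, SVMConfig(kernel_degree=1, box_constraint=1.0))
            accs.append(m.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_single_perfect_feature_gives_perfect_metrics(self):
        table = _pair_table(effect=0.0)
        table["ppm"] = np.where(table["group"] == "MDD", 5.0, -5.0)
        folds = make_grouped_stratified_folds(table, k=5, seed=0)
        m = crossval_evaluate(table, folds, SVMConfig(kernel_degree=1, box_constraint=1.0))
        assert m.accuracy == 1.0
        assert m.precision == 1.0
        assert m.recall == 1.0
        assert m.f1 == 1.0

    def test_f1_is_harmonic_mean_per_fold(self):
        table = _pair_table(effect=0.8, seed=2)
        folds = make_grouped_stratified_folds(table, k=5, seed=2)
        m = crossval_evaluate(table, folds, SVMConfig(kernel_degree=2, box_constraint=1.0))
        for _, row in m.per_fold.iterrows():
            p, r = row["precision"], row["recall"]
            if p > 0 and r > 0:
                assert row["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-9)

    def test_positive_class_convention(self):
        assert positive_class(("HC", "SSD")) == "SSD"
        assert positive_class(("HC", "MDD")) == "MDD"
        assert positive_class(("MDD", "SSD")) == "MDD"


class TestRepetitions:
    def test_fixed_master_seed_reproduces_metrics(self):
        table = _pair_table(effect=1.0, seed=5)
        cfg = SVMConfig(kernel_degree=1, box_constraint=1.0)
        m1, _ = repeat_pipeline(table, cfg, n_reps=2, master_seed=9)
        m2, _ = repeat_pipeline(table, cfg, n_reps=2, master_seed=9)
        pd.testing.assert_frame_equal(m1, m2)

    def test_metric_spread_shrinks_with_more_repetitions(self):
        # sampling theory: the SE of the mean over n_reps independent fold
        # seeds scales ~ 1/sqrt(n_reps); check the spread ratio at 10 vs 40
        table = _pair_table(effect=0.7, seed=6)
        cfg = SVMConfig(kernel_degree=1, box_constraint=1.0)
        means_small, means_large = [], []
        for chunk in range(4):
            m10, _ = repeat_pipeline(table, cfg, n_reps=10, master_seed=100 + chunk)
            m40, _ = repeat_pipeline(table, cfg, n_reps=40, master_seed=200 + chunk)
            means_small.append(m10["accuracy"].mean())
            means_large.append(m40["accuracy"].mean())
        se_small = np.std(means_small)
        se_large = np.std(means_large)
        assert se_large < se_small * 1.2  # allow noise around the 2x prediction

    def test_degree3_not_much_worse_than_degree1_on_separated_data(self):
        table = _pair_table(effect=2.2, rho=0.2, seed=4)
        accs = {}
        for d in (1, 3):
            m, _ = repeat_pipeline(
                table, SVMConfig(kernel_degree=d, box_constraint=1.0),
                n_reps=3, master_seed=11,
            )
            accs[d] = m["accuracy"].mean()
        assert accs[3] >= accs[1] - 0.05
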