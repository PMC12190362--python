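"""Self-reporting, failureAlert forest, overlapdiff, and evaluation statistics."""

import numpy as np
import pytest

from fundusmosaic.errors import InputError, UndefinedValueError
from fundusmosaic.failure_detection import (RegistrationReport, auc_score,
                                            evaluate_contingency, failure_alert,
                                            make_synthetic_covariates,
                                            overlapdiff, self_report,
                                            train_failure_forest,
                                            unaware_failure_pct)


class TestSelfReport:
    @pytest.mark.parametrize("n_matches,n_inliers,expected", [
        (0, 0, True),       # no matched points at all
        (200, 150, False),  # healthy run
        (5, 3, True),       # below the 4-point minimal homography sample
        (4, 4, False),      # exactly estimable
    ])
    def test_rule(self, n_matches, n_inliers, expected):
        assert self_report(n_matches, n_inliers) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            self_report(-1, 0)


class TestOverlapdiff:
    def test_equal_is_zero(self):
        assert overlapdiff(0.55, 0.55) == 0.0

    def test_percentage_points(self):
        assert overlapdiff(0.55, 0.48) == pytest.approx(7.0)

    def test_symmetric(self):
        a = RegistrationReport(method="vessel", overlap_pct=0.61)
        b = RegistrationReport(method="affine_nmi", overlap_pct=0.44)
        assert overlapdiff(a, b) == overlapdiff(b, a)

    def test_missing_overlap_undefined(self):
        a = RegistrationReport(method="vessel", overlap_pct=None)
        b = RegistrationReport(method="affine_nmi", overlap_pct=0.5)
        with pytest.raises(UndefinedValueError):
            overlapdiff(a, b)


class TestForest:
    def test_separable_covariates_high_oob_auc(self):
        for seed in range(5):
            table, labels = make_synthetic_covariates(n_rows=500, seed=seed)
            model = train_failure_forest(table, labels, seed=seed)
            assert model.oob_auc >= 0.95

    def test_permuted_labels_chance_auc(self):
        for seed in range(5):
            table, labels = make_synthetic_covariates(n_rows=500, seed=seed)
            rng = np.random.default_rng(seed)
            model = train_failure_forest(table, rng.permutation(labels), seed=seed)
            assert 0.4 <= model.oob_auc <= 0.6

    def test_deterministic_under_seed(self):
        table, labels = make_synthetic_covariates(n_rows=200, seed=1)
        m1 = train_failure_forest(table, labels, n_trees=100, seed=7)
        m2 = train_failure_forest(table, labels, n_trees=100, seed=7)
        assert m1.selected_covariates == m2.selected_covariates
        row = table.iloc[10].to_dict()
        assert failure_alert(m1, row) == failure_alert(m2, row)

    def test_single_class_rejected(self):
        table, labels = make_synthetic_covariates(n_rows=100, seed=0)
        with pytest.raises(InputError):
            train_failure_forest(table, np.ones(100, bool), seed=0)


@pytest.fixture(scope="module")
def model_and_table():
    table, labels = make_synthetic_covariates(n_rows=300, seed=2)
    return train_failure_forest(table, labels, n_trees=100, seed=2), table


class TestFailureAlert:
    def test_extremes(self, model_and_table):
        model, table = model_and_table
        clear_success = table[:5]   # drawn from the success block
        clear_failure = table[-5:]  # drawn from the failure block
        for _, row in clear_success.iterrows():
            assert failure_alert(model, row.to_dict()) <= 0.2
        for _, row in clear_failure.iterrows():
            assert failure_alert(model, row.to_dict()) >= 0.8

    def test_equals_per_tree_vote_oracle(self, model_and_table):
        model, table = model_and_table
        x = np.array([[table.iloc[42][c] for c in model.selected_covariates]])
        votes = 0
        for tree in model.forest.estimators_:
            cls = model.forest.classes_[int(np.argmax(tree.predict_proba(x)[0]))]
            votes += int(cls == 1)
        expected = 1.0 - votes / len(model.forest.estimators_)
        assert failure_alert(model, table.iloc[42].to_dict()) == expected

    def test_missing_covariate_named(self, model_and_table):
        model, table = model_and_table
        row = table.iloc[0].to_dict()
        first = model.selected_covariates[0]
        del row[first]
        with pytest.raises(InputError, match=first):
            failure_alert(model, row)


class TestContingency:
    def test_published_style_cells(self):
        # cells: both succeed 3197, A-only 183, B-only 154, both fail 36
        a = [True] * 3380 + [False] * 190
        b = [True] * 3197 + [False] * 183 + [True] * 154 + [False] * 36
        summary = evaluate_contingency(a, b)
        assert summary.cells.tolist() == [[3197, 183], [154, 36]]
        assert round(summary.method_a_success_pct, 1) == 94.7
        assert round(summary.method_b_success_pct, 1) == 93.9
        assert round(summary.joint_failure_pct, 0) == 1.0
        assert round(summary.at_least_one_success_pct, 0) == 99.0

    def test_all_success(self):
        s = evaluate_contingency([True] * 10, [True] * 10)
        assert s.method_a_success_pct == 100.0
        assert s.joint_failure_pct == 0.0
        assert s.at_least_one_success_pct == 100.0

    def test_counting_oracle(self, rng):
        a = rng.random(500) < 0.9
        b = rng.random(500) < 0.85
        s = evaluate_contingency(a, b)
        cells = [[0, 0], [0, 0]]
        for x, y in zip(a, b):
            cells[0 if x else 1][0 if y else 1] += 1
        assert s.cells.tolist() == cells

    def test_unaware_failure_rate(self):
        assert unaware_failure_pct(190, 165, 3570) == pytest.approx(0.7, abs=0.05)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            evaluate_contingency([True], [True, False])


class TestAucScore:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        assert auc_score(scores, labels) == 1.0

    def test_independent_scores_chance_level(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.random(2000)
            labels = r.random(2000) < 0.3
            assert 0.45 <= auc_score(scores, labels) <= 0.55

    def test_sign_reversal_flips_auc(self, rng):
        scores = rng.random(300)
        labels = (scores + rng.normal(0, 0.3, 300)) > 0.6
        a = auc_score(scores, labels)
        b = auc_score(-scores, labels)
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_extra_regressor_never_lowers_in_sample_auc(self, rng):
        scores = rng.random(400)
        extra = rng.random(400)
        labels = (0.7 * scores + 0.3 * extra + rng.normal(0, 0.2, 400)) > 0.6
        base = auc_score(scores, labels)
        joint = auc_score(scores, labels, extra=extra)
        assert joint >= base - 1e-9

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedValueError):
            auc_score([0.1, 0.2], [True, True])
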