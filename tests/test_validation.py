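"""Cross-validation protocol, micro-accuracy, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from opscc_cdm import (
    BayesianNetwork,
    DiscreteVariable,
    LearningConfig,
    ModelError,
    PatientDataset,
    auc,
    cross_validate,
    make_folds,
    micro_accuracy,
    roc_points,
)


class TestMakeFolds:
    def test_94_records_10_folds_sizes(self):
        folds = make_folds(94, 10, seed=1)
        sizes = sorted(
            (np.asarray(folds.labels) == f).sum() for f in range(10)
        )
        assert sizes == [9] * 6 + [10] * 4  # 94 = 4*10 + 6*9

    def test_one_record_per_fold_when_n_equals_k(self):
        folds = make_folds(7, 7, seed=0)
        assert sorted(folds.labels) == list(range(7))

    def test_deterministic_given_seed(self):
        assert make_folds(50, 5, seed=9).labels == make_folds(50, 5, seed=9).labels
        assert make_folds(50, 5, seed=9).labels != make_folds(50, 5, seed=10).labels

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            make_folds(5, 6, seed=0)
        with pytest.raises(ModelError):
            make_folds(5, 1, seed=0)


class TestMicroAccuracy:
    @pytest.mark.parametrize(
        "correct, total, printed",
        [(249, 470, 0.529), (283, 470, 0.602), (332, 376, 0.883), (0, 100, 0.0)],
    )
    def test_pooled_proportions(self, correct, total, printed):
        assert micro_accuracy(correct, total) == pytest.approx(printed, abs=1e-3)

    def test_errors(self):
        with pytest.raises(ModelError):
            micro_accuracy(1, 0)
        with pytest.raises(ModelError):
            micro_accuracy(5, 4)


class TestRoc:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_points([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert (0.0, 1.0) in pts
        assert auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]).value == 1.0

    def test_all_tied_scores_single_group(self):
        pts = roc_points([0.5] * 4, [True, False, True, False])
        assert pts == [(0.0, 0.0), (1.0, 1.0)]
        assert auc([0.5] * 4, [True, False, True, False]).value == 0.5

    def test_four_record_hand_case(self):
        scores, labels = [0.9, 0.8, 0.4, 0.2], [True, False, True, False]
        pts = roc_points(scores, labels)
        assert pts == [(0, 0), (0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]
        assert auc(scores, labels).value == pytest.approx(0.75)  # 3 of 4 pairs

    def test_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        pts = roc_points(scores, labels)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        xs, ys = zip(*pts)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))

    def test_one_class_flagged_not_numeric(self):
        """A target with a single observed class has no defined AUC — the
        rare-therapy failure mode is surfaced, not silently scored."""
        result = auc([0.2, 0.4, 0.9], [False, False, False])
        assert result.degenerate and result.value is None
        assert (result.n_pos, result.n_neg) == (0, 3)
        with pytest.raises(ModelError):
            roc_points([0.2, 0.4], [True, True])

    def test_trapezoid_equals_tie_corrected_concordance(self):
        """AUC identity with the Mann-Whitney U statistic (ties counted as
        half) on randomized score vectors, including heavy ties."""
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(5, 60))
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), int(rng.integers(1, 3)))
            ours = auc(scores, labels).value
            u, _p = mannwhitneyu(
                scores[labels], scores[~labels], alternative="two-sided"
            )
            mw = u / (labels.sum() * (~labels).sum())
            assert ours == pytest.approx(mw, abs=1e-12)


def _deterministic_setup(n=120, seed=0):
    """Binary evidence E fully determines target T; all configs observed."""
    e = DiscreteVariable("E", ("e1", "e2"))
    t = DiscreteVariable("T", ("true", "false"), role="target")
    net = BayesianNetwork([e, t], edges=[("E", "T")])
    rng = np.random.default_rng(seed)
    ev = rng.choice(["e1", "e2"], n)
    df = pd.DataFrame({"E": ev, "T": np.where(ev == "e1", "true", "false")})
    return net, PatientDataset(df)


class TestCrossValidate:
    def test_perfectly_learnable_dataset_scores_one(self):
        net, ds = _deterministic_setup()
        report = cross_validate(net, ds, ["T"], k=10, seed=0)
        assert report.overall_accuracy == 1.0
        assert report.per_target["T"].auc.value == 1.0

    def test_shuffled_labels_near_chance(self):
        """Balanced binary labels independent of the evidence give pooled
        accuracy ~0.5 (permutation null)."""
        rng = np.random.default_rng(8)
        n = 200
        e = DiscreteVariable("E", ("e1", "e2"))
        t = DiscreteVariable("T", ("true", "false"), role="target")
        net = BayesianNetwork([e, t], edges=[("E", "T")])
        df = pd.DataFrame(
            {
                "E": rng.choice(["e1", "e2"], n),
                "T": rng.permutation(["true", "false"] * (n // 2)),
            }
        )
        report = cross_validate(net, PatientDataset(df), ["T"], k=10, seed=8)
        assert report.overall_accuracy == pytest.approx(0.5, abs=0.1)

    def test_report_conservation_and_reproducibility(self):
        net, ds = _deterministic_setup(n=94)
        report = cross_validate(net, ds, ["T"], k=10, seed=3)
        assert report.overall_total == 94 * 1
        assert sum(f.total for f in report.folds) == report.overall_total
        assert report.overall_correct == sum(
            t.correct for t in report.per_target.values()
        )
        again = cross_validate(net, ds, ["T"], k=10, seed=3)
        assert again.to_json_dict() == report.to_json_dict()

    def test_rare_class_target_isolated(self):
        """Two positives placed independently of the evidence leave that
        target's AUC near chance (or undefined) while a learnable target in
        the same model is unaffected."""
        rng = np.random.default_rng(21)
        n = 94
        e = DiscreteVariable("E", ("e1", "e2"))
        good = DiscreteVariable("good", ("true", "false"), role="target")
        rare = DiscreteVariable("rare", ("true", "false"), role="target")
        net = BayesianNetwork(
            [e, good, rare], edges=[("E", "good"), ("E", "rare")]
        )
        ev = rng.choice(["e1", "e2"], n)
        rare_labels = np.array(["false"] * n, dtype=object)
        rare_labels[rng.choice(n, 2, replace=False)] = "true"
        df = pd.DataFrame(
            {
                "E": ev,
                "good": np.where(ev == "e1", "true", "false"),
                "rare": rare_labels,
            }
        )
        report = cross_validate(
            net, PatientDataset(df), ["good", "rare"], k=10, seed=21
        )
        rare_auc = report.per_target["rare"].auc
        assert rare_auc.n_pos == 2
        # the rare therapy is not reliably scored: AUC undefined or poor,
        # and both positive patients are mispredicted (majority class wins)
        assert rare_auc.value is None or rare_auc.value <= 0.75
        assert report.per_target["rare"].correct == n - 2
        assert report.per_target["good"].accuracy == 1.0
        assert report.per_target["good"].auc.value == 1.0

    def test_unknown_target_rejected(self):
        net, ds = _deterministic_setup()
        with pytest.raises(ModelError):
            cross_validate(net, ds, ["Z"], k=5, seed=0)

    def test_report_text_and_json_render(self):
        net, ds = _deterministic_setup(n=40)
        report = cross_validate(net, ds, ["T"], k=4, seed=0)
        text = report.to_text()
        assert "overall accuracy" in text and "T" in text
        blob = report.to_json_dict()
        assert blob["overall"]["total"] == 40
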