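"""Tenfold cross-validation of therapy-target predictions.

For each fold, CPTs are learned on the remaining folds; each held-out
patient's target nodes are then predicted from evidence on *all non-target
variables* (therapy decisions are never used as evidence for one another,
matching clinical use where no decision is known in advance).  Correctness
is MAP state versus the recorded state — for Boolean targets this is the
0.5-threshold rule — and results are pooled micro-style: correct
(patient, target) pairs over all such pairs.

Per target, the posterior score of the positive state (the first declared
state, ``true`` for Boolean therapy nodes) is collected over all held-out
patients, giving a pooled ROC curve and trapezoidal AUC.  The AUC equals the
tie-corrected concordance probability P(score+ > score-) + 0.5 P(tie); a
target with only one observed class has no defined AUC and is flagged
instead (the small-cohort failure mode of very rare therapy options).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import BayesianNetwork, ModelError, infer_posterior
from .learning import DataError, LearningConfig, PatientDataset, learn_cpts


@dataclass(frozen=True)
class FoldAssignment:
    """Reproducible shuffled round-robin fold labels (sizes differ by <=1)."""

    k: int
    labels: tuple[int, ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) != fold)


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Assign ``n`` records to ``k`` folds by shuffled round-robin."""
    if not 1 < k <= n:
        raise ModelError(f"need 1 < k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % k
    return FoldAssignment(k, tuple(int(x) for x in labels), seed)


def micro_accuracy(correct: int, total: int) -> float:
    """Pooled proportion of correct (patient, target) predictions.

    Returns the exact ratio; reports format it to 3 decimals."""
    if total <= 0:
        raise ModelError("total must be positive")
    if not 0 <= correct <= total:
        raise ModelError(f"need 0 <= correct <= total, got {correct}/{total}")
    return correct / total


def roc_points(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float]]:
    """ROC curve (FPR, TPR) points from (0,0) to (1,1), ties grouped.

    Thresholds sweep the distinct scores; requires at least one positive and
    one negative label."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ModelError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)]


@dataclass(frozen=True)
class AucResult:
    """AUC with degeneracy flag: ``value`` is None when only one class was
    observed (e.g. a therapy received by too few patients to score)."""

    value: float | None
    n_pos: int
    n_neg: int

    @property
    def degenerate(self) -> bool:
        return self.value is None


def auc(scores: Sequence[float], labels: Sequence[bool]) -> AucResult:
    """Trapezoidal area under the ROC curve.

    Equals the tie-corrected concordance probability
    ``P(score+ > score-) + 0.5 * P(score+ = score-)``; one-class input yields
    a flagged, undefined AUC rather than an arbitrary number."""
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return AucResult(None, n_pos, n_neg)
    pts = roc_points(scores, labels)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return AucResult(float(np.trapezoid(ys, xs)), n_pos, n_neg)


@dataclass
class TargetResult:
    """Per-target pooled counts, scores and ROC summary."""

    name: str
    correct: int
    total: int
    scores: list[float]
    truths: list[bool]
    auc: AucResult
    roc: list[tuple[float, float]]

    @property
    def accuracy(self) -> float:
        return micro_accuracy(self.correct, self.total)


@dataclass
class FoldResult:
    fold: int
    n_test: int
    correct: int
    total: int


@dataclass
class ValidationReport:
    """Cross-validation outcome over all (patient, target) pairs."""

    targets: list[str]
    per_target: dict[str, TargetResult]
    folds: list[FoldResult]
    n_records: int
    k: int
    seed: int
    alpha: float

    @property
    def overall_correct(self) -> int:
        return sum(t.correct for t in self.per_target.values())

    @property
    def overall_total(self) -> int:
        return sum(t.total for t in self.per_target.values())

    @property
    def overall_accuracy(self) -> float:
        return micro_accuracy(self.overall_correct, self.overall_total)

    def to_json_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "k": self.k,
            "seed": self.seed,
            "alpha": self.alpha,
            "targets": self.targets,
            "overall": {
                "correct": self.overall_correct,
                "total": self.overall_total,
                "accuracy": round(self.overall_accuracy, 3),
            },
            "per_target": {
                name: {
                    "correct": t.correct,
                    "total": t.total,
                    "accuracy": round(t.accuracy, 3),
                    "auc": None if t.auc.degenerate else round(t.auc.value, 3),
                    "n_pos": t.auc.n_pos,
                    "n_neg": t.auc.n_neg,
                }
                for name, t in self.per_target.items()
            },
            "folds": [
                {"fold": f.fold, "n_test": f.n_test, "correct": f.correct,
                 "total": f.total}
                for f in self.folds
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation, n={self.n_records}, "
            f"seed={self.seed}, alpha={self.alpha}",
            f"overall accuracy: {self.overall_accuracy:.3f} "
            f"({self.overall_correct}/{self.overall_total})",
            "",
            f"{'target':<32}{'accuracy':>10}{'AUC':>10}{'pos':>6}{'neg':>6}",
        ]
        for name, t in self.per_target.items():
            auc_s = "undef" if t.auc.degenerate else f"{t.auc.value:.3f}"
            lines.append(
                f"{name:<32}{t.accuracy:>10.3f}{auc_s:>10}"
                f"{t.auc.n_pos:>6}{t.auc.n_neg:>6}"
            )
        return "\n".join(lines)


def cross_validate(
    network: BayesianNetwork,
    dataset: PatientDataset,
    targets: Sequence[str],
    k: int = 10,
    seed: int = 0,
    config: LearningConfig = LearningConfig(),
) -> ValidationReport:
    """k-fold cross-validation of MAP predictions for the target nodes.

    Reproducible bit-for-bit from (dataset, structure, k, seed, alpha);
    the report totals always equal ``n_records * len(targets)``.
    """
    for t in targets:
        network.variable(t)
    dataset.validate_against(network)
    if not dataset.covers(network):
        missing = [n for n in network.variable_names if n not in dataset.columns]
        raise DataError(f"dataset lacks columns for variables: {missing}")
    targets = list(targets)
    target_set = set(targets)
    evidence_cols = [
        n for n in network.variable_names if n not in target_set
    ]
    assignment = make_folds(dataset.n_records, k, seed)

    scores: dict[str, list[float]] = {t: [] for t in targets}
    truths: dict[str, list[bool]] = {t: [] for t in targets}
    correct: dict[str, int] = {t: 0 for t in targets}
    folds: list[FoldResult] = []
    for fold in range(k):
        train_idx = assignment.train_indices(fold)
        if len(train_idx) == 0:
            raise ModelError(f"fold {fold} has an empty training set")
        train = PatientDataset(dataset.df.iloc[train_idx], dataset.provenance)
        fitted = learn_cpts(network, train, config)
        fold_correct = 0
        test_idx = assignment.test_indices(fold)
        for i in test_idx:
            row = dataset.df.iloc[int(i)]
            evidence = {c: row[c] for c in evidence_cols}
            for t in targets:
                tvar = network.variable(t)
                posterior = infer_posterior(fitted, evidence, t)
                positive = tvar.states[0]
                scores[t].append(posterior[positive])
                truths[t].append(row[t] == positive)
                values = [posterior[s] for s in tvar.states]
                predicted = tvar.states[int(np.argmax(values))]
                if predicted == row[t]:
                    correct[t] += 1
                    fold_correct += 1
        folds.append(
            FoldResult(fold, len(test_idx), fold_correct,
                       len(test_idx) * len(targets))
        )

    per_target: dict[str, TargetResult] = {}
    for t in targets:
        result = auc(scores[t], truths[t])
        roc = (
            roc_points(scores[t], truths[t]) if not result.degenerate else []
        )
        per_target[t] = TargetResult(
            t, correct[t], dataset.n_records, scores[t], truths[t], result, roc
        )
    return ValidationReport(
        targets, per_target, folds, dataset.n_records, k, seed, config.alpha
    )
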