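"""Data-splitting protocol and evaluation metrics.

Known interactions are positives; all unknown drug-protein pairs form the
negative universe. 20% of positives (with an equal number of sampled
negatives) are held out as an independent test set; the remaining positives
are partitioned into 5 cross-validation folds, each validated against an
equal number of negatives drawn once from the remaining pool. Per fold the
validation (and test) positives are masked out of A_DP before the network
is rebuilt, so no held-out label can leak into encoder training.

Metrics: ROC-AUC (probability a random positive outscores a random
negative, ties at 1/2), PR-AUC (area under the precision-recall step curve
by descending-score sweep), and threshold-0.5 F1 / accuracy / recall.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .classifier import ForestConfig, fit_forest, predict_scores
from .encoder import EncoderConfig, encode, fuse, train_encoder
from .hetnet import build_hetnet, node_features
from .io_formats import InteractionTable
from .similarity import SimilarityMatrix

Pair = tuple[str, str]
LabeledPair = tuple[Pair, int]


@dataclass
class SplitPlan:
    """Independent test set plus 5 cross-validation folds, all fixed by seed."""

    test_pairs: list[LabeledPair]
    folds: list[tuple[list[LabeledPair], list[LabeledPair]]]  # (train, validation)
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def all_negative_pairs(drug_ids: list[str], protein_ids: list[str],
                       positives: set[Pair]) -> list[Pair]:
    """Every unknown (drug, protein) pair, in deterministic grid order."""
    return [(d, p) for d in drug_ids for p in protein_ids if (d, p) not in positives]


def make_splits(
    positives: list[Pair],
    negatives_pool: list[Pair],
    seed: int,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> SplitPlan:
    """Build the test/CV split plan used throughout evaluation.

    Training negatives for each fold are sampled 1:1 with that fold's
    training positives, excluding the test negatives and the fold's own
    validation negatives.
    """
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positive pairs")
    rng = np.random.default_rng(seed)
    pos = list(positives)
    rng.shuffle(pos)
    n_test = int(round(test_fraction * len(pos)))
    test_pos, cv_pos = pos[:n_test], pos[n_test:]

    neg = list(negatives_pool)
    rng.shuffle(neg)
    if len(neg) < len(pos) * 2:
        raise ValueError("negative pool too small for the requested splits")
    cursor = 0

    def take(k: int) -> list[Pair]:
        nonlocal cursor
        out = neg[cursor : cursor + k]
        cursor += k
        return out

    test_neg = take(len(test_pos))
    fold_pos = [list(part) for part in np.array_split(np.arange(len(cv_pos)), n_folds)]
    fold_val_pos = [[cv_pos[i] for i in idx] for idx in fold_pos]
    fold_val_neg = [take(len(vp)) for vp in fold_val_pos]

    folds: list[tuple[list[LabeledPair], list[LabeledPair]]] = []
    held_neg = set(test_neg)
    for f in range(n_folds):
        val_pos = fold_val_pos[f]
        val_neg = fold_val_neg[f]
        train_pos = [p for g in range(n_folds) if g != f for p in fold_val_pos[g]]
        excluded = held_neg | set(val_neg)
        train_neg: list[Pair] = []
        for cand in neg[cursor:]:
            if cand not in excluded:
                train_neg.append(cand)
            if len(train_neg) == len(train_pos):
                break
        if len(train_neg) < len(train_pos):
            raise ValueError("negative pool exhausted while sampling training negatives")
        train = [(p, 1) for p in train_pos] + [(p, 0) for p in train_neg]
        val = [(p, 1) for p in val_pos] + [(p, 0) for p in val_neg]
        folds.append((train, val))
    test = [(p, 1) for p in test_pos] + [(p, 0) for p in test_neg]
    return SplitPlan(test_pairs=test, folds=folds, seed=seed)


# -- metrics ---------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC: P(random positive outscores random negative)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))

def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve (descending-score sweep)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("pr_auc requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """(F1, accuracy, recall) with predictions positive iff score >= threshold.

    F1 is defined as 0 when precision or recall is undefined.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    accuracy = (tp + tn) / len(labels)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return f1, accuracy, recall


@dataclass
class EvalReport:
    roc_auc: float
    pr_auc: float
    f1: float
    accuracy: float
    recall: float
    threshold: float = 0.5
    n_pos: int = 0
    n_neg: int = 0
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


def score_report(scores, labels, threshold: float = 0.5,
                 seed: int | None = None) -> EvalReport:
    labels = np.asarray(labels).astype(int)
    f1, acc, rec = threshold_metrics(scores, labels, threshold)
    return EvalReport(
        roc_auc=roc_auc(scores, labels), pr_auc=pr_auc(scores, labels),
        f1=f1, accuracy=acc, recall=rec, threshold=threshold,
        n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()), seed=seed,
    )


def mean_report(reports: list[EvalReport]) -> EvalReport:
    return EvalReport(
        roc_auc=float(np.mean([r.roc_auc for r in reports])),
        pr_auc=float(np.mean([r.pr_auc for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        n_pos=sum(r.n_pos for r in reports),
        n_neg=sum(r.n_neg for r in reports),
        seed=reports[0].seed if reports else None,
    )


def best_report(reports: list[EvalReport]) -> EvalReport:
    """The optimistically-selected best fold (highest ROC-AUC)."""
    return max(reports, key=lambda r: r.roc_auc)


# -- end-to-end fold execution ---------------------------------------------


def run_fold(
    s_d: SimilarityMatrix,
    s_p: SimilarityMatrix,
    train: list[LabeledPair],
    eval_pairs: list[LabeledPair],
    encoder_config: EncoderConfig,
    forest_config: ForestConfig,
    extra_edges: InteractionTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on one fold and score its held-out pairs.

    A_DP is built from the fold's training positives only, so validation and
    test interactions are invisible during encoding.
    """
    train_positives = {pair for pair, y in train if y == 1}
    table = InteractionTable(edges=set(train_positives))
    if extra_edges is not None:
        table.drug_drug_edges = set(extra_edges.drug_drug_edges)
        table.target_target_edges = set(extra_edges.target_target_edges)
    net = build_hetnet(s_d, s_p, table)
    F = node_features(net)
    model, _ = train_encoder(net, F, train, encoder_config)
    emb = encode(net, F, model)
    Z_train = fuse(emb, [pair for pair, _ in train])
    y_train = np.array([y for _, y in train])
    forest = fit_forest(Z_train, y_train, forest_config)
    Z_eval = fuse(emb, [pair for pair, _ in eval_pairs])
    scores = predict_scores(forest, Z_eval)
    labels = np.array([y for _, y in eval_pairs])
    return scores, labels


def run_cross_validation(
    s_d: SimilarityMatrix,
    s_p: SimilarityMatrix,
    plan: SplitPlan,
    encoder_config: EncoderConfig,
    forest_config: ForestConfig,
    extra_edges: InteractionTable | None = None,
) -> tuple[list[EvalReport], EvalReport]:
    """Run the 5-fold protocol; returns per-fold reports and their mean."""
    reports = []
    for f, (train, val) in enumerate(plan.folds):
        try:
            scores, labels = run_fold(s_d, s_p, train, val, encoder_config,
                                      forest_config, extra_edges)
        except Exception as exc:
            raise RuntimeError(f"fold {f}: {exc}") from exc
        reports.append(score_report(scores, labels, seed=plan.seed))
    return reports, mean_report(reports)
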