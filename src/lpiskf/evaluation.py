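"""Cross-validation protocols, ranking metrics and top-k case-study ranking.

Three 5-fold schemes are provided: *pairwise* (known interactions split into
folds and masked), *novel-lncrna* and *novel-protein* (whole entities held
out, their adjacency rows/columns zeroed, emulating prediction for entities
with no known partner).  The interaction-profile (GIP) kernels are recomputed
from the masked adjacency inside each fold — the only channel through which
held-out labels could leak — while the expression, alignment and feature
kernels, which do not depend on the adjacency, are computed once.

The negative class follows the semi-supervised convention: every pair never
observed positive is treated as a negative at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import InteractionDataset
from .fusion import SkfParams, fuse_kernels
from .laprls import LaprlsParams, predict_bipartite
from .similarity import SimilarityKernel, gip_kernel

logger = logging.getLogger(__name__)

SCHEMES = ("pairwise", "novel-lncrna", "novel-protein")


@dataclass
class FoldPlan:
    """Partition of positives (pairwise) or entities (novel-*) into folds."""

    scheme: str
    folds: list[list]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes}")

    @property
    def sizes(self) -> list[int]:
        return [len(f) for f in self.folds]


@dataclass
class EvalReport:
    """Pooled ranking metrics plus per-fold provenance."""

    auroc: float
    aupr: float
    precision: float
    recall: float
    f1: float
    threshold: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    scheme: str = "pairwise"
    per_fold: list[dict] = field(default_factory=list)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def auroc_fold_mean(self) -> float:
        vals = [f["auroc"] for f in self.per_fold if f.get("auroc") is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> str:
        lines = [
            f"scheme            {self.scheme}",
            f"AUROC (pooled)    {self.auroc:.4f}",
            f"AUROC (fold mean) {self.auroc_fold_mean:.4f}",
            f"AUPR  (pooled)    {self.aupr:.4f}",
            f"best-F1 threshold {self.threshold:.6g}",
            f"precision         {self.precision:.4f}",
            f"recall            {self.recall:.4f}",
            f"F1                {self.f1:.4f}",
            f"TP/FP/FN/TN       {self.tp}/{self.fp}/{self.fn}/{self.tn}",
        ]
        return "\n".join(lines)


def _split(items: list, n_folds: int, seed: int) -> list[list]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    return [[items[i] for i in chunk] for chunk in np.array_split(perm, n_folds)]


def pair_folds(dataset: InteractionDataset, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly partition the known interactions into balanced folds."""
    positives = dataset.positives()
    if len(positives) < n_folds:
        raise ValueError(f"only {len(positives)} positives for {n_folds} folds")
    return FoldPlan("pairwise", _split(positives, n_folds, seed), n_folds, seed)


def entity_folds(dataset: InteractionDataset, axis: str, n_folds: int = 5,
                 seed: int = 0) -> FoldPlan:
    """Randomly partition the entities on one axis into balanced folds."""
    if axis == "lncrna":
        count, scheme = dataset.n, "novel-lncrna"
    elif axis == "protein":
        count, scheme = dataset.m, "novel-protein"
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if count < n_folds:
        raise ValueError(f"only {count} entities for {n_folds} folds")
    return FoldPlan(scheme, _split(list(range(count)), n_folds, seed), n_folds, seed)


def mask_fold(dataset: InteractionDataset, plan: FoldPlan, fold: int) -> np.ndarray:
    """Training adjacency with the fold's positives (or entity rows/columns) zeroed."""
    A = dataset.A.copy()
    if plan.scheme == "pairwise":
        for i, j in plan.folds[fold]:
            A[i, j] = 0.0
    elif plan.scheme == "novel-lncrna":
        A[list(plan.folds[fold]), :] = 0.0
    else:
        A[:, list(plan.folds[fold])] = 0.0
    return A


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: need both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR undefined: need both classes present")
    return float(average_precision_score(labels, scores))


def precision_recall_f1(scores, labels, threshold: float) -> tuple[float, float, float]:
    """Precision, recall and F1 for the decision rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not labels.any():
        raise ValueError("no positives: recall undefined")
    called = scores >= threshold
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    fn = int(np.sum(~called & labels))
    if tp + fp == 0:
        logger.warning("no pairs called positive at threshold %g; precision set to 0", threshold)
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    rec = tp / (tp + fn)
    f1 = 0.0 if pre + rec == 0 else 2.0 * pre * rec / (pre + rec)
    return pre, rec, f1


def best_f1_threshold(scores, labels) -> tuple[float, EvalReport]:
    """Scan all unique score values for the F1-maximizing threshold.

    Ties in F1 are broken toward the lower threshold.  Returns the threshold
    and a full report evaluated at it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best = (-1.0, np.inf)  # (f1, threshold)
    for t in np.unique(scores):
        _, _, f1 = precision_recall_f1(scores, labels, t)
        if f1 > best[0] or (f1 == best[0] and t < best[1]):
            best = (f1, float(t))
    threshold = best[1]
    pre, rec, f1 = precision_recall_f1(scores, labels, threshold)
    called = scores >= threshold
    lab = labels.astype(bool)
    report = EvalReport(
        auroc=auroc(scores, labels), aupr=aupr(scores, labels),
        precision=pre, recall=rec, f1=f1, threshold=threshold,
        tp=int(np.sum(called & lab)), fp=int(np.sum(called & ~lab)),
        fn=int(np.sum(~called & lab)), tn=int(np.sum(~called & ~lab)),
        scores=scores, labels=labels,
    )
    return threshold, report


def top_k_predictions(F: np.ndarray, A_train: np.ndarray, k: int,
                      lncrna_ids=None, protein_ids=None) -> list[tuple]:
    """The k highest-scoring pairs not already known, descending.

    Ties are broken deterministically by (row, column) index.
    """
    F = np.asarray(F, dtype=float)
    A_train = np.asarray(A_train)
    rows, cols = np.nonzero(A_train == 0)
    vals = F[rows, cols]
    order = np.lexsort((cols, rows, -vals))[:k]
    out = []
    for o in order:
        i, j = int(rows[o]), int(cols[o])
        lid = lncrna_ids[i] if lncrna_ids is not None else i
        pid = protein_ids[j] if protein_ids is not None else j
        out.append((lid, pid, float(vals[o])))
    return out


def _fold_pipeline(dataset: InteractionDataset, A_train: np.ndarray,
                   lncrna_kernels: list[SimilarityKernel],
                   protein_kernels: list[SimilarityKernel],
                   skf_l: SkfParams, skf_p: SkfParams,
                   laprls_params: LaprlsParams) -> np.ndarray:
    """Recompute GIP kernels from the masked adjacency, re-fuse, re-solve."""
    train = InteractionDataset(dataset.lncrna_ids, dataset.protein_ids, A_train)
    gip_l = gip_kernel(train, "lncrna")
    gip_p = gip_kernel(train, "protein")
    fused_l, _ = fuse_kernels([gip_l, *lncrna_kernels], skf_l)
    fused_p, _ = fuse_kernels([gip_p, *protein_kernels], skf_p)
    return predict_bipartite(fused_l, fused_p, train, laprls_params).F


def run_cv(dataset: InteractionDataset,
           lncrna_kernels: list[SimilarityKernel],
           protein_kernels: list[SimilarityKernel],
           skf_l: SkfParams, skf_p: SkfParams,
           laprls_params: LaprlsParams,
           plan: FoldPlan,
           include_train_negatives: bool = False) -> EvalReport:
    """Execute a full cross-validation and return pooled metrics.

    In the pairwise scheme every positive is scored exactly once, in the fold
    where it is held out; each never-positive cell is scored in every fold
    and its scores are averaged into one pooled value.  In the novel-entity
    schemes every cell of a held-out row/column is scored exactly once.  By
    default the current fold's training positives are excluded from the
    evaluation pool; ``include_train_negatives`` adds them as negatives.
    """
    A = dataset.A
    n, m = A.shape
    if plan.scheme == "pairwise":
        pos_scores: list[float] = []
        neg_acc = np.zeros((n, m))
        train_neg_scores: list[float] = []
        per_fold = []
        never_pos = A == 0
        for f in range(plan.n_folds):
            A_train = mask_fold(dataset, plan, f)
            F = _fold_pipeline(dataset, A_train, lncrna_kernels, protein_kernels,
                               skf_l, skf_p, laprls_params)
            test_pos = plan.folds[f]
            fold_pos = [float(F[i, j]) for i, j in test_pos]
            pos_scores.extend(fold_pos)
            neg_acc += F * never_pos
            fold_scores = np.concatenate([fold_pos, F[never_pos]])
            fold_labels = np.concatenate([np.ones(len(fold_pos)), np.zeros(int(never_pos.sum()))])
            per_fold.append({
                "fold": f, "n_test_positives": len(fold_pos),
                "auroc": auroc(fold_scores, fold_labels) if len(fold_pos) else None,
                "aupr": aupr(fold_scores, fold_labels) if len(fold_pos) else None,
            })
            if include_train_negatives:
                train_pos = [(i, j) for g in range(plan.n_folds) if g != f
                             for (i, j) in plan.folds[g]]
                train_neg_scores.extend(float(F[i, j]) for i, j in train_pos)
        neg_scores = neg_acc[never_pos] / plan.n_folds
        scores = np.concatenate([pos_scores, neg_scores, train_neg_scores])
        labels = np.concatenate([np.ones(len(pos_scores)),
                                 np.zeros(neg_scores.size + len(train_neg_scores))])
    else:
        scores_list: list[float] = []
        labels_list: list[float] = []
        per_fold = []
        for f in range(plan.n_folds):
            A_train = mask_fold(dataset, plan, f)
            held = list(plan.folds[f])
            if plan.scheme == "novel-lncrna":
                assert not A_train[held, :].any()
            else:
                assert not A_train[:, held].any()
            F = _fold_pipeline(dataset, A_train, lncrna_kernels, protein_kernels,
                               skf_l, skf_p, laprls_params)
            if plan.scheme == "novel-lncrna":
                fold_scores = F[held, :].ravel()
                fold_labels = A[held, :].ravel()
            else:
                fold_scores = F[:, held].ravel()
                fold_labels = A[:, held].ravel()
            scores_list.extend(fold_scores.tolist())
            labels_list.extend(fold_labels.tolist())
            both = len(np.unique(fold_labels)) == 2
            per_fold.append({
                "fold": f, "n_test_positives": int(fold_labels.sum()),
                "auroc": auroc(fold_scores, fold_labels) if both else None,
                "aupr": aupr(fold_scores, fold_labels) if both else None,
            })
        scores = np.asarray(scores_list)
        labels = np.asarray(labels_list)
    threshold, report = best_f1_threshold(scores, labels)
    report.scheme = plan.scheme
    report.per_fold = per_fold
    return report
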