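"""Fivefold cross-validation of the link predictor.

Positives are the 1-cells of the scored MD layer (known plus recommended
associations in the full model; known only in the resource-allocation
baseline), negatives are all remaining 0-cells — no negative subsampling.
Both classes are shuffled and split into k near-equal folds.  Per fold, the
test positives are masked to 0 in a training copy of the MD matrix, the
allocation scores are recomputed on that masked matrix (the collaborative
filtering stage is fixed before splitting and not re-run), and the final
scores at all test cells are evaluated by ROC AUC and area under the
precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .collaborative import densify
from .graph import STAGE_UPDATED, TripartiteGraph
from .resource import allocate

MODES = ("cf_ra", "ra_only")


@dataclass
class FoldAssignment:
    """Fold labels (0..k-1) over flat cell indices of the MD matrix."""

    pos_cells: np.ndarray  # flat indices of positive cells, one fold label each
    pos_folds: np.ndarray
    neg_cells: np.ndarray
    neg_folds: np.ndarray
    k: int
    seed: int

    def test_cells(self, fold_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(test positive cells, test negative cells) for one fold."""
        return (
            self.pos_cells[self.pos_folds == fold_id],
            self.neg_cells[self.neg_folds == fold_id],
        )


@dataclass
class CVResult:
    """Per-fold, per-repeat and overall AUC/AUPR."""

    per_fold: list[list[tuple[float, float]]]  # [repeat][fold] -> (auc, aupr)
    gamma: float
    mode: str
    seed: int
    per_repeat: list[tuple[float, float]] = field(init=False)
    auc_mean: float = field(init=False)
    auc_sd: float = field(init=False)
    aupr_mean: float = field(init=False)
    aupr_sd: float = field(init=False)
    auc_max: float = field(init=False)
    aupr_max: float = field(init=False)

    def __post_init__(self) -> None:
        reps = np.array(
            [[np.mean([a for a, _ in rep]), np.mean([p for _, p in rep])] for rep in self.per_fold]
        )
        self.per_repeat = [tuple(row) for row in reps]
        self.auc_mean, self.aupr_mean = reps.mean(axis=0)
        self.auc_sd, self.aupr_sd = reps.std(axis=0, ddof=0)
        self.auc_max, self.aupr_max = reps.max(axis=0)


def _fold_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k near-equal fold labels (sizes differ by <= 1) in shuffled order."""
    labels = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    rng.shuffle(labels)
    return labels


def make_folds(g_u: TripartiteGraph, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle positives and negatives separately into k near-equal folds."""
    if g_u.stage != STAGE_UPDATED:
        raise ValueError("folds are drawn over the scored (updated) graph")
    flat = g_u.A_MD.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    if len(pos) < k:
        raise ValueError(f"need at least {k} positives, found {len(pos)}")
    if len(neg) < k:
        raise ValueError(f"need at least {k} negatives, found {len(neg)}")
    rng = np.random.default_rng(seed)
    return FoldAssignment(
        pos_cells=pos,
        pos_folds=_fold_labels(len(pos), k, rng),
        neg_cells=neg,
        neg_folds=_fold_labels(len(neg), k, rng),
        k=k,
        seed=seed,
    )


def run_fold(
    g_u: TripartiteGraph,
    folds: FoldAssignment,
    fold_id: int,
    gamma: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask the fold's test positives, rescore, return (scores, labels) at test cells.

    The training copy never reads the masked cells, so a test positive's
    score is computed without using its own edge.
    """
    if not 0 <= fold_id < folds.k:
        raise ValueError(f"fold_id must be in 0..{folds.k - 1}")
    test_pos, test_neg = folds.test_cells(fold_id)
    train = g_u.copy()
    md = train.A_MD.ravel()
    md[test_pos] = 0
    scores = allocate(train, gamma=gamma).values.ravel()
    cells = np.concatenate([test_pos, test_neg])
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
    return scores[cells], labels


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """ROC AUC (trapezoid over the tie-grouped threshold sweep) and area under
    the precision-recall step curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def run_cv(
    g: TripartiteGraph,
    gamma: float = 0.9,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    mode: str = "cf_ra",
    p_denominator: str = "all_rows",
) -> CVResult:
    """Repeated k-fold cross-validation from the initial graph G0.

    mode="cf_ra" densifies G0 once (positives = known + recommended) before
    splitting; mode="ra_only" skips collaborative filtering (positives =
    known associations only).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "cf_ra":
        g_u = densify(g, p_denominator=p_denominator)
    else:
        g_u = g.copy(stage=STAGE_UPDATED)

    root = np.random.SeedSequence(seed)
    per_fold: list[list[tuple[float, float]]] = []
    for child in root.spawn(repeats):
        fold_seed = int(child.generate_state(1)[0] % (2**31))
        folds = make_folds(g_u, k=k, seed=fold_seed)
        rep = []
        for fold_id in range(k):
            scores, labels = run_fold(g_u, folds, fold_id, gamma=gamma)
            rep.append(roc_pr_curves(scores, labels))
        per_fold.append(rep)
    return CVResult(per_fold=per_fold, gamma=gamma, mode=mode, seed=seed)
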