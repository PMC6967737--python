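"""Cross-validated evaluation and candidate ranking.

Known associations are split into k folds; each fold is masked out of A,
the Gaussian kernels and integrated similarities are recomputed on the
masked matrix (so the held-out signal cannot leak through the kernels),
the walk reruns, and the held-out positives are scored against every pair
that is 0 in the full A (training positives are excluded from scoring).
AUC uses the Mann–Whitney rank statistic with midranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import Dataset
from .walk_core import WalkParams

__all__ = ["FoldAssignment", "CvResult", "kfold_split", "roc_auc", "cross_validate", "rank_candidates"]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the known (miRNA, disease) pairs into k folds of sizes
    differing by at most one, deterministic given the seed."""

    k: int
    assignment: dict[tuple[str, str], int]
    seed: int

    def pairs_in_fold(self, fold: int) -> list[tuple[str, str]]:
        return [p for p, f in self.assignment.items() if f == fold]


@dataclass(frozen=True)
class CvResult:
    per_fold_auc: list[float]
    mean_auc: float
    params: WalkParams
    seed: int


def kfold_split(a: pd.DataFrame, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition of the positive entries of A into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rows, cols = np.nonzero(a.to_numpy())
    positives = [(a.index[i], a.columns[j]) for i, j in zip(rows, cols)]
    if len(positives) < k:
        raise ValueError(f"cannot split {len(positives)} positives into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    assignment = {positives[idx]: (pos % k) + 1 for pos, idx in enumerate(order)}
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def cross_validate(
    dataset: Dataset,
    params: WalkParams | None = None,
    k: int = 5,
    seed: int = 0,
    delta: float = 0.5,
    gamma_d: float = 1.0,
    gamma_m: float = 1.0,
    combine: str = "sum",
    semantic_aggregate: str = "max",
    permute_labels: bool = False,
) -> CvResult:
    """k-fold cross-validation of the full pipeline.

    Per fold: the fold's positives are zeroed in A, the kernels and the walk
    are recomputed on the masked matrix, and the fold's positives (label 1)
    are pooled with every pair that is 0 in the full A (label 0) into one
    global AUC.  ``permute_labels=True`` shuffles the label vector before
    scoring — a calibration control whose AUC should sit near 0.5.
    """
    from .estimator import ThreeLayerRandomWalk

    params = params or WalkParams()
    dataset.validate()
    folds = kfold_split(dataset.a, k, seed)
    a_full = dataset.a.to_numpy()
    row_pos = {name: i for i, name in enumerate(dataset.a.index)}
    col_pos = {name: j for j, name in enumerate(dataset.a.columns)}
    est = ThreeLayerRandomWalk(
        alpha=params.alpha,
        beta=params.beta,
        lam=params.lam,
        l=params.l,
        r=params.r,
        s=params.s,
        delta=delta,
        gamma_d=gamma_d,
        gamma_m=gamma_m,
        combine=combine,
        semantic_aggregate=semantic_aggregate,
    )
    null_rng = np.random.default_rng(seed + 1_000_003) if permute_labels else None
    per_fold: list[float] = []
    for fold in range(1, k + 1):
        test_pairs = folds.pairs_in_fold(fold)
        if not test_pairs:
            raise ValueError(f"fold {fold} has no positives")
        a_train = a_full.copy()
        for m, d in test_pairs:
            a_train[row_pos[m], col_pos[d]] = 0.0
        a_train_df = pd.DataFrame(a_train, index=dataset.a.index, columns=dataset.a.columns)
        est.fit(dataset, a_train=a_train_df)
        md = est.score_matrix_.to_numpy()

        test_mask = np.zeros_like(a_full, dtype=bool)
        for m, d in test_pairs:
            test_mask[row_pos[m], col_pos[d]] = True
        neg_mask = a_full == 0
        scored = test_mask | neg_mask
        labels = test_mask[scored].astype(int)
        scores = md[scored]
        if permute_labels:
            labels = null_rng.permutation(labels)
        per_fold.append(roc_auc(scores, labels))
    return CvResult(
        per_fold_auc=per_fold,
        mean_auc=float(np.mean(per_fold)),
        params=params,
        seed=seed,
    )


def rank_candidates(
    md: pd.DataFrame,
    a: pd.DataFrame,
    disease: str,
    top_n: int = 50,
) -> list[tuple[str, float]]:
    """Top candidate miRNAs for one disease, by predicted score.

    miRNAs already associated with the disease in A are excluded; the rest
    are sorted by score descending with ties broken by name ascending, and
    the list is truncated to ``top_n``.
    """
    if disease not in md.columns:
        raise ValueError(f"unknown disease {disease!r}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    known = set(a.index[a[disease].to_numpy() != 0]) if disease in a.columns else set()
    candidates = [(m, float(md.at[m, disease])) for m in md.index if m not in known]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:top_n]
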