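"""Estimator front end for the three-layer walk.

``ThreeLayerRandomWalk`` packages the whole pipeline — similarity
construction, Laplace normalization, inter-network prior, unbalanced walk —
as a scikit-learn style estimator: hyperparameters in ``__init__`` (visible
to ``get_params``/``set_params`` and model selection), data consumed by
``fit``, results in trailing-underscore attributes.  The method is
transductive: ``fit`` takes the full association bundle and the fitted
``score_matrix_`` covers every miRNA × disease pair in it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io_formats import Dataset
from .similarity import (
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    lncrna_similarity,
    ss1_matrix,
    ss2_matrix,
)
from .transition import laplace_normalize
from .walk_core import WalkParams, bnetwalk, tcrwmda_walk

__all__ = ["ThreeLayerRandomWalk"]


class ThreeLayerRandomWalk(BaseEstimator):
    """miRNA–disease association scoring by unbalanced random walk on a
    miRNA / lncRNA / disease heterogeneous network.

    Parameters
    ----------
    alpha, beta, lam : float in [0, 1]
        Walk-vs-restart mixing weights: ``alpha`` for the intra-network walk,
        ``beta`` for the lncRNA-layer walk, ``lam`` for the weight of the
        inter-network prior R against the raw association matrix A.
    l, r, s : int >= 0
        Fixed step counts of the miRNA-side, disease-side and inter-network
        walks (the walk is "unbalanced" because l and r may differ).
    delta : float in (0, 1]
        Per-level attenuation of ancestor contributions in the first disease
        semantic model.
    gamma_d, gamma_m : float > 0
        Bandwidth scale of the Gaussian interaction-profile kernels on the
        disease and miRNA axes of A.
    combine : {"sum", "mean"}
        How the indicator-gated left/right branches are merged at each step.
    semantic_aggregate : {"max", "sum"}
        Child-aggregation rule of the first semantic model's recursion.

    Attributes
    ----------
    score_matrix_ : DataFrame (n_mirna × n_disease)
        Predicted association scores; higher means more likely associated.
    sm_, sd_, sl_ : DataFrame
        Integrated miRNA, disease and lncRNA similarity networks.
    r_prior_ : DataFrame
        The inter-network (lncRNA-bridged) prior R.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 0.1,
        lam: float = 0.9,
        l: int = 1,
        r: int = 1,
        s: int = 1,
        delta: float = 0.5,
        gamma_d: float = 1.0,
        gamma_m: float = 1.0,
        combine: str = "sum",
        semantic_aggregate: str = "max",
    ):
        self.alpha = alpha
        self.beta = beta
        self.lam = lam
        self.l = l
        self.r = r
        self.s = s
        self.delta = delta
        self.gamma_d = gamma_d
        self.gamma_m = gamma_m
        self.combine = combine
        self.semantic_aggregate = semantic_aggregate

    def _walk_params(self) -> WalkParams:
        return WalkParams(
            alpha=self.alpha, beta=self.beta, lam=self.lam, l=self.l, r=self.r, s=self.s
        )

    def fit(self, dataset: Dataset, y=None, a_train: pd.DataFrame | None = None):
        """Build the similarity networks and run the walk.

        ``a_train`` optionally substitutes a masked copy of the miRNA–disease
        matrix (cross-validation training folds) while ``dataset.a`` keeps
        the full ground truth; kernels and the walk use ``a_train`` only.
        """
        if not isinstance(dataset, Dataset):
            raise TypeError("fit expects a Dataset bundle")
        dataset.validate()
        self._walk_params()  # validates walk hyperparameters
        if self.gamma_d <= 0 or self.gamma_m <= 0:
            raise ValueError("gamma_d and gamma_m must be positive")

        a = dataset.a if a_train is None else a_train
        if not (a.index.equals(dataset.a.index) and a.columns.equals(dataset.a.columns)):
            raise ValueError("a_train must share dataset.a's indices")

        diseases = list(dataset.diseases)
        self.sl_ = lncrna_similarity(dataset.sequences, dataset.lncrnas)
        self.has_semantics_ = np.array([d in dataset.dags for d in diseases])
        self.ss1_ = ss1_matrix(dataset.dags, diseases, self.delta, self.semantic_aggregate)
        self.ss2_ = ss2_matrix(dataset.dags, len(diseases), diseases)
        self.kd_ = gip_kernel(a, axis="cols", gamma_prime=self.gamma_d)
        self.km_ = gip_kernel(a, axis="rows", gamma_prime=self.gamma_m)
        self.sd_ = integrate_disease_similarity(self.ss1_, self.ss2_, self.kd_, self.has_semantics_)
        self.sm_ = integrate_mirna_similarity(dataset.fs, self.km_)

        params = self._walk_params()
        l_trans = laplace_normalize(self.sl_.to_numpy())
        m_trans = laplace_normalize(self.sm_.to_numpy())
        d_trans = laplace_normalize(self.sd_.to_numpy())
        r = bnetwalk(dataset.b, dataset.c, l_trans, beta=self.beta, s=self.s)
        md = tcrwmda_walk(a, m_trans, d_trans, r, params, combine=self.combine)
        self.r_prior_ = pd.DataFrame(r, index=a.index, columns=a.columns)
        self.score_matrix_ = pd.DataFrame(md, index=a.index, columns=a.columns)
        self.n_features_in_ = a.shape[0] * a.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray | pd.DataFrame:
        """Scores for (miRNA, disease) name pairs, or the full score matrix
        when ``X`` is None."""
        check_is_fitted(self, "score_matrix_")
        if X is None:
            return self.score_matrix_.copy()
        scores = np.empty(len(X))
        for i, (m, d) in enumerate(X):
            try:
                scores[i] = self.score_matrix_.at[m, d]
            except KeyError as exc:
                raise ValueError(f"unknown entity in pair ({m!r}, {d!r})") from exc
        return scores

    def rank_candidates(self, a: pd.DataFrame, disease: str, top_n: int = 50):
        """Top candidate miRNAs for a disease, excluding known associations."""
        check_is_fitted(self, "score_matrix_")
        from .evaluation import rank_candidates

        return rank_candidates(self.score_matrix_, a, disease, top_n)
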