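"""The unbalanced random walk on the three-layer heterogeneous network.

Two fixed-step walks make the prediction:

* ``bnetwalk`` — the inter-network walk.  The miRNA–lncRNA prior B and
  lncRNA–disease prior C are each propagated through the lncRNA transition
  matrix L for s steps (mixing weight β against the prior) and composed into
  a miRNA × disease score matrix R = ML · LD.
* ``tcrwmda_walk`` — the walk on the heterogeneous network.  Starting from
  MD⁰ = A / ΣA, a left step propagates through the miRNA transition matrix M
  for up to l steps and a right step through the disease transition matrix D
  for up to r steps; each step mixes walking (weight α) with the composite
  prior λ·R + (1−λ)·A, and at step t the active branches (t ≤ l, t ≤ r) are
  indicator-gated and summed.

Step counts are fixed (no convergence test); the walks are fully
deterministic linear recurrences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transition import laplace_normalize

__all__ = ["WalkParams", "bnetwalk", "tcrwmda_walk", "predict"]


@dataclass(frozen=True)
class WalkParams:
    """Hyperparameters of the unbalanced walk.

    alpha : mixing weight of the intra-network walk term (restart weight 1−alpha)
    beta : mixing weight of the lncRNA-network walk inside bnetwalk
    lam : weight of the inter-network prior R against the raw associations A
    l, r : step counts of the miRNA-side (left) and disease-side (right) walks
    s : step count of the inter-network walk
    """

    alpha: float = 0.1
    beta: float = 0.1
    lam: float = 0.9
    l: int = 1
    r: int = 1
    s: int = 1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("l", "r", "s"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if max(self.l, self.r) < 1:
            raise ValueError("no walk steps: max(l, r) must be >= 1")


def _as_array(x) -> np.ndarray:
    return x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


def bnetwalk(
    b,
    c,
    l_trans,
    beta: float = 0.1,
    s: int = 1,
) -> np.ndarray:
    """Inter-network walk through the lncRNA layer.

    ML⁰ = B/ΣB and LD⁰ = C/ΣC; for t = 1..s,
    ML^t = β·ML^{t−1}·L + (1−β)·B and LD^t = β·L·LD^{t−1} + (1−β)·C;
    the result is R = ML^s · LD^s (s = 0 composes the normalized priors).
    """
    b = _as_array(b)
    c = _as_array(c)
    l_trans = _as_array(l_trans)
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if s < 0:
        raise ValueError("s must be >= 0")
    if b.shape[1] != l_trans.shape[0] or l_trans.shape[1] != c.shape[0]:
        raise ValueError("dimension mismatch along the lncRNA axis")
    b_total, c_total = b.sum(), c.sum()
    if b_total == 0 or c_total == 0:
        raise ValueError("empty prior: B and C must each contain at least one association")
    ml = b / b_total
    ld = c / c_total
    for _ in range(s):
        ml = beta * (ml @ l_trans) + (1.0 - beta) * b
        ld = beta * (l_trans @ ld) + (1.0 - beta) * c
    return ml @ ld


def tcrwmda_walk(
    a,
    m_trans,
    d_trans,
    r_prior,
    params: WalkParams,
    combine: str = "sum",
) -> np.ndarray:
    """Indicator-gated unbalanced walk on the three-layer network.

    MD⁰ = A/ΣA; for t = 1..max(l, r),
    left  = α·M·MD^{t−1} + (1−α)·[λ·R + (1−λ)·A]   (active while t ≤ l)
    right = α·MD^{t−1}·D + (1−α)·[λ·R + (1−λ)·A]   (active while t ≤ r)
    and MD^t is the sum of the active branches (``combine='sum'``, the
    printed recurrence — MD doubles in scale while both branches run) or
    their mean (``combine='mean'``); rankings within a branch regime are
    unaffected.  R is a constant prior, precomputed once.
    """
    a = _as_array(a)
    m_trans = _as_array(m_trans)
    d_trans = _as_array(d_trans)
    r_prior = _as_array(r_prior)
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    if a.shape != r_prior.shape:
        raise ValueError("prior R must have A's shape")
    if m_trans.shape != (a.shape[0], a.shape[0]) or d_trans.shape != (a.shape[1], a.shape[1]):
        raise ValueError("transition matrices must match A's miRNA/disease dimensions")
    a_total = a.sum()
    if a_total == 0:
        raise ValueError("empty prior: A must contain at least one association")
    restart = (1.0 - params.alpha) * (params.lam * r_prior + (1.0 - params.lam) * a)
    md = a / a_total
    for t in range(1, max(params.l, params.r) + 1):
        terms = []
        if t <= params.l:
            terms.append(params.alpha * (m_trans @ md) + restart)
        if t <= params.r:
            terms.append(params.alpha * (md @ d_trans) + restart)
        md = sum(terms)
        if combine == "mean":
            md = md / len(terms)
    return md


def predict(
    a: pd.DataFrame,
    b: pd.DataFrame,
    c: pd.DataFrame,
    sm: pd.DataFrame,
    sd: pd.DataFrame,
    sl: pd.DataFrame,
    params: WalkParams | None = None,
    combine: str = "sum",
) -> pd.DataFrame:
    """Full pipeline: Laplace-normalize the three similarity networks, run
    the inter-network walk for the prior R, then the unbalanced walk.

    Returns the predicted miRNA × disease score matrix over A's indices.
    """
    params = params or WalkParams()
    m_trans = laplace_normalize(_as_array(sm))
    d_trans = laplace_normalize(_as_array(sd))
    l_trans = laplace_normalize(_as_array(sl))
    r_prior = bnetwalk(b, c, l_trans, beta=params.beta, s=params.s)
    md = tcrwmda_walk(a, m_trans, d_trans, r_prior, params, combine=combine)
    return pd.DataFrame(md, index=a.index, columns=a.columns)
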