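"""Intra-layer similarity networks.

Three similarity matrices feed the walk:

* **lncRNA** — cosine similarity of 20-dimensional sequence-composition
  vectors (4 mononucleotide + 16 overlapping-dinucleotide proportions).
* **disease** — the mean of two DAG-based semantic models where both diseases
  carry MeSH-like annotation, with the Gaussian interaction-profile (GIP)
  kernel as fallback.  Model 1 attenuates an ancestor's contribution by Δ
  per level; model 2 weights a term by its information content
  −log(fraction of disease DAGs containing it).
* **miRNA** — a precomputed functional-similarity matrix (MISIM-style) where
  available, GIP kernel elsewhere.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io_formats import DiseaseDAG

__all__ = [
    "MONONUCLEOTIDES",
    "DINUCLEOTIDES",
    "sequence_composition",
    "cosine_similarity_matrix",
    "lncrna_similarity",
    "semantic_value_model1",
    "ss1_matrix",
    "semantic_value_model2",
    "ss2_matrix",
    "gip_kernel",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
]

MONONUCLEOTIDES = tuple("ACGT")
#: lexicographic AA, AC, AG, AT, CA, ..., TT
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

def sequence_composition(sequence: str) -> np.ndarray:
    """20-dimensional composition vector of a nucleotide sequence.

    The first 4 entries are mononucleotide proportions (A, C, G, T), the
    remaining 16 are overlapping-dinucleotide proportions in lexicographic
    order.  U maps to T; case is ignored; windows touching any other symbol
    are excluded from both numerator and denominator, so each block sums to
    1 whenever at least one valid window exists.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    mono = np.zeros(4)
    valid = 0
    pos = {c: i for i, c in enumerate(MONONUCLEOTIDES)}
    for ch in seq:
        i = pos.get(ch)
        if i is not None:
            mono[i] += 1
            valid += 1
    if valid == 0:
        raise ValueError("sequence contains no valid A/C/G/T/U nucleotides")
    mono /= valid
    di = np.zeros(16)
    di_valid = 0
    for k in range(len(seq) - 1):
        i, j = pos.get(seq[k]), pos.get(seq[k + 1])
        if i is not None and j is not None:
            di[4 * i + j] += 1
            di_valid += 1
    if di_valid:
        di /= di_valid
    return np.concatenate([mono, di])


def cosine_similarity_matrix(
    features: Sequence[np.ndarray] | np.ndarray,
    names: Sequence[str],
) -> pd.DataFrame:
    """Pairwise cosine similarity of nonnegative feature vectors.

    With nonnegative inputs every entry lands in [0, 1]; the diagonal is
    exactly 1.  A zero-norm vector is an error (ruled out upstream by
    ``sequence_composition``).
    """
    f = np.asarray(features, dtype=float)
    norms = np.linalg.norm(f, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm feature vector")
    sim = (f @ f.T) / np.outer(norms, norms)
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return pd.DataFrame(sim, index=list(names), columns=list(names))


def lncrna_similarity(sequences: Mapping[str, str], names: Sequence[str]) -> pd.DataFrame:
    """Sequence-composition cosine similarity over the given lncRNA index."""
    missing = [n for n in names if n not in sequences]
    if missing:
        raise ValueError(f"missing sequences for lncRNA(s): {missing[:5]}")
    feats = [sequence_composition(sequences[n]) for n in names]
    return cosine_similarity_matrix(feats, names)


def semantic_value_model1(
    dag: DiseaseDAG,
    delta: float = 0.5,
    aggregate: str = "max",
) -> tuple[dict[str, float], float]:
    """Per-term semantic contributions D1 within one disease's DAG, plus DV1.

    The root contributes 1; every ancestor term contributes Δ times the
    aggregated contribution of its children inside the DAG.  ``aggregate``
    is ``max`` (the established Wang-style definition) or ``sum``.
    DV1 is the total over T(D).
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    contrib: dict[str, float] = {}
    # child->parent edges: topological order yields children before parents
    for term in nx.topological_sort(dag.graph):
        if term == dag.root:
            contrib[term] = 1.0
            continue
        child_vals = [delta * contrib[c] for c in dag.graph.predecessors(term)]
        if not child_vals:
            raise ValueError(f"term {term!r} unreachable from root {dag.root!r}")
        contrib[term] = max(child_vals) if aggregate == "max" else sum(child_vals)
    return contrib, float(sum(contrib.values()))


def ss1_matrix(
    dags: Mapping[str, DiseaseDAG],
    names: Sequence[str],
    delta: float = 0.5,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Semantic-similarity model 1 over the disease index.

    SS1(i,j) = Σ_{d ∈ T(i)∩T(j)} (D1_i(d) + D1_j(d)) / (DV1(i) + DV1(j)).
    Pairs where either disease lacks a DAG are NaN; the integration step
    masks them with the GIP kernel.
    """
    names = list(names)
    contribs = {d: semantic_value_model1(dags[d], delta, aggregate) for d in dags if d in set(names)}
    n = len(names)
    out = np.full((n, n), np.nan)
    for i, di in enumerate(names):
        if di not in contribs:
            continue
        ci, dvi = contribs[di]
        for j in range(i, n):
            dj = names[j]
            if dj not in contribs:
                continue
            cj, dvj = contribs[dj]
            shared = ci.keys() & cj.keys()
            num = sum(ci[d] + cj[d] for d in shared)
            out[i, j] = out[j, i] = num / (dvi + dvj)
        out[i, i] = 1.0
    return pd.DataFrame(out, index=names, columns=names)


def semantic_value_model2(
    dags: Mapping[str, DiseaseDAG],
    n_diseases: int,
) -> tuple[dict[str, float], dict[str, float]]:
    """Information-content contributions D2 and per-disease totals DV2.

    D2(d) = −log(k_d / n_diseases) where k_d counts the disease DAGs that
    contain term d; the contribution is root-independent.  Natural log —
    the base cancels in the SS2 ratio.
    """
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    counts: dict[str, int] = {}
    for dag in dags.values():
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    d2: dict[str, float] = {}
    for term, k in counts.items():
        if k > n_diseases:
            raise ValueError(f"term {term!r} appears in {k} DAGs but only {n_diseases} diseases exist")
        d2[term] = -np.log(k / n_diseases)
    dv2 = {root: float(sum(d2[t] for t in dag.nodes)) for root, dag in dags.items()}
    return d2, dv2


def ss2_matrix(
    dags: Mapping[str, DiseaseDAG],
    n_diseases: int,
    names: Sequence[str],
) -> pd.DataFrame:
    """Semantic-similarity model 2 over the disease index.

    SS2(i,j) = Σ_{d ∈ T(i)∩T(j)} 2·D2(d) / (DV2(i) + DV2(j)); diagonal 1.
    When DV2(i) = DV2(j) = 0 (every term appears in every DAG) the
    off-diagonal value is defined as 0.
    """
    names = list(names)
    d2, dv2 = semantic_value_model2(dags, n_diseases)
    n = len(names)
    out = np.full((n, n), np.nan)
    for i, di in enumerate(names):
        if di not in dags:
            continue
        ti = dags[di].nodes
        for j in range(i, n):
            dj = names[j]
            if dj not in dags:
                continue
            denom = dv2[di] + dv2[dj]
            if denom == 0.0:
                out[i, j] = out[j, i] = 0.0
            else:
                shared = ti & dags[dj].nodes
                out[i, j] = out[j, i] = sum(2.0 * d2[d] for d in shared) / denom
        out[i, i] = 1.0
    return pd.DataFrame(out, index=names, columns=names)


def gip_kernel(
    assoc: pd.DataFrame,
    axis: str = "rows",
    gamma_prime: float = 1.0,
) -> pd.DataFrame:
    """Gaussian interaction-profile kernel over one axis of an association matrix.

    The profile of an entity is its binary row (``axis='rows'``) or column
    (``axis='cols'``) of the association matrix; the bandwidth is
    γ = γ′ / (mean squared profile norm), so K(i,j) = exp(−γ‖IP(i)−IP(j)‖²).
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if axis == "rows":
        profiles = assoc.to_numpy(dtype=float)
        names = list(assoc.index)
    elif axis == "cols":
        profiles = assoc.to_numpy(dtype=float).T
        names = list(assoc.columns)
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("bandwidth undefined: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    k = np.exp(-gamma * sq_dists)
    np.fill_diagonal(k, 1.0)
    k = (k + k.T) / 2.0
    return pd.DataFrame(k, index=names, columns=names)


def _check_aligned(*matrices: pd.DataFrame) -> None:
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("similarity matrices must share the same entity index")


def integrate_disease_similarity(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    kd: pd.DataFrame,
    has_semantics: Sequence[bool] | np.ndarray,
) -> pd.DataFrame:
    """Integrated disease similarity: mean of SS1 and SS2 where both diseases
    carry semantic annotation, GIP kernel value otherwise; diagonal 1."""
    _check_aligned(ss1, ss2, kd)
    flags = np.asarray(has_semantics, dtype=bool)
    if flags.shape != (len(kd),):
        raise ValueError("has_semantics length must match the disease index")
    both = np.outer(flags, flags)
    semantic = (ss1.to_numpy() + ss2.to_numpy()) / 2.0
    sd = np.where(both, semantic, kd.to_numpy())
    if np.isnan(sd).any():
        raise ValueError("semantic similarity undefined for a flagged disease pair")
    np.fill_diagonal(sd, 1.0)
    return pd.DataFrame(sd, index=kd.index, columns=kd.columns)


def integrate_mirna_similarity(
    fs: pd.DataFrame,
    km: pd.DataFrame,
    has_functional: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrated miRNA similarity: functional similarity where the pair is
    covered, GIP kernel elsewhere; diagonal 1.

    ``fs`` is aligned to the kernel's miRNA index by name; miRNAs missing
    from it fall through to the kernel.  The default coverage mask is
    FS > 0 plus the diagonal; an explicit mask overrides it.
    """
    fs_aligned = fs.reindex(index=km.index, columns=km.columns)
    fs_vals = fs_aligned.to_numpy(dtype=float)
    known = ~np.isnan(fs_vals)
    if np.any((fs_vals[known] < 0) | (fs_vals[known] > 1)):
        raise ValueError("functional-similarity entries must lie in [0, 1]")
    if has_functional is None:
        mask = known & (np.nan_to_num(fs_vals) > 0)
        np.fill_diagonal(mask, True)
    else:
        mask = (
            has_functional.reindex(index=km.index, columns=km.columns)
            .fillna(False)
            .to_numpy(dtype=bool)
            if isinstance(has_functional, pd.DataFrame)
            else np.asarray(has_functional, dtype=bool)
        )
        mask = mask & known
    sm = np.where(mask, np.nan_to_num(fs_vals), km.to_numpy())
    np.fill_diagonal(sm, 1.0)
    sm = (sm + sm.T) / 2.0
    return pd.DataFrame(sm, index=km.index, columns=km.columns)
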