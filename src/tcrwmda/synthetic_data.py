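"""Self-contained synthetic datasets with planted group structure.

The generator emulates the *shape* of the real inputs — three sparse binary
association matrices (miRNA–disease, miRNA–lncRNA, lncRNA–disease) over
shared entity indices, lncRNA sequences, disease DAGs and a functional-
similarity matrix — with a latent block structure that every data source
reflects: entities belong to groups, within-group associations are denser
than cross-group ones (p_in vs p_out), sequences carry a group-specific
nucleotide bias, same-group diseases share DAG ancestors, and the
functional-similarity matrix is high within groups.  The pipeline should
therefore rank held-out within-group pairs highly, which makes full
cross-validation testable with no external download.

One seed drives everything; independent sub-streams are derived per
component so adding one matrix never shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    Dataset,
    _dags_from_graph,
    align_dataset,
    read_association_edgelist,
    read_dag_edges,
    read_fasta,
    read_named_matrix,
    write_association_edgelist,
    write_dag_edges,
    write_fasta,
    write_named_matrix,
)

__all__ = ["SynthConfig", "generate_dataset", "write_bundle", "read_bundle", "BUNDLE_FILES"]

_NUCS = "ACGT"

BUNDLE_FILES = {
    "a": "mirna_disease.tsv",
    "b": "mirna_lncrna.tsv",
    "c": "lncrna_disease.tsv",
    "fasta": "lncrna_sequences.fasta",
    "dag": "disease_dag.tsv",
    "fs": "mirna_functional_similarity.tsv",
    "entities": "entities.tsv",
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    p_in / p_out are the within-group / cross-group association rates used
    for all three matrices; fs_in / fs_out are the planted functional-
    similarity levels.  Defaults give a 50×40×10 bundle with 4 groups that
    a full 5-fold cross-validation handles in seconds.
    """

    n_mirna: int = 50
    n_disease: int = 40
    n_lncrna: int = 10
    n_groups: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seq_length: int = 300
    dag_depth: int = 3
    seed: int = 1
    fs_in: float = 0.8
    fs_out: float = 0.1

    def validate(self) -> None:
        # p_out == p_in is allowed: it removes the planted signal entirely,
        # the reference condition for null calibration
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if min(self.n_mirna, self.n_disease, self.n_lncrna) < self.n_groups:
            raise ValueError("every entity count must be >= n_groups")
        if self.seq_length < 2:
            raise ValueError("seq_length must be >= 2")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")


def _names(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _block_bernoulli(rng, row_groups, col_groups, p_in, p_out) -> np.ndarray:
    same = row_groups[:, None] == col_groups[None, :]
    p = np.where(same, p_in, p_out)
    return (rng.random(p.shape) < p).astype(float)


def _balanced_groups(rng, n: int, k: int) -> np.ndarray:
    """Shuffled equal allocation: every group gets floor(n/k) or ceil(n/k)
    entities, so the planted block structure exists in every layer."""
    return rng.permutation(np.arange(n) % k)


#: distinct favoured nucleotide pair per group (up to 6 groups cycle)
_GROUP_PAIRS = [("A", "C"), ("G", "T"), ("A", "G"), ("C", "T"), ("A", "T"), ("C", "G")]


def _group_sequence(rng, group: int, length: int) -> str:
    """First-order Markov sequence biased toward a group-specific dinucleotide.

    With probability 0.7 the chain alternates within the group's favoured
    nucleotide pair, otherwise it jumps uniformly; the dinucleotide block of
    the composition vector then concentrates on the pair's two transitions,
    so sequence cosine similarity separates the groups.
    """
    a, b = _GROUP_PAIRS[group % len(_GROUP_PAIRS)]
    cur = a if rng.random() < 0.5 else b
    out = [cur]
    for _ in range(length - 1):
        if rng.random() < 0.7:
            if cur == a:
                cur = b
            elif cur == b:
                cur = a
            else:
                cur = a if rng.random() < 0.5 else b
        else:
            cur = _NUCS[rng.integers(4)]
        out.append(cur)
    return "".join(out)


def generate_dataset(cfg: SynthConfig) -> tuple[Dataset, dict[str, int]]:
    """Generate a bundle; returns (dataset, entity→group map).

    Deterministic given ``cfg.seed``: the same config always yields the
    same bundle, byte-identical once written.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(6)]
    rng_groups, rng_a, rng_b, rng_c, rng_seq, _spare = streams

    mirnas = _names("mirna_", cfg.n_mirna)
    diseases = _names("disease_", cfg.n_disease)
    lncrnas = _names("lnc_", cfg.n_lncrna)

    g_m = _balanced_groups(rng_groups, cfg.n_mirna, cfg.n_groups)
    g_d = _balanced_groups(rng_groups, cfg.n_disease, cfg.n_groups)
    g_l = _balanced_groups(rng_groups, cfg.n_lncrna, cfg.n_groups)

    a = pd.DataFrame(
        _block_bernoulli(rng_a, g_m, g_d, cfg.p_in, cfg.p_out), index=mirnas, columns=diseases
    )
    b = pd.DataFrame(
        _block_bernoulli(rng_b, g_m, g_l, cfg.p_in, cfg.p_out), index=mirnas, columns=lncrnas
    )
    c = pd.DataFrame(
        _block_bernoulli(rng_c, g_l, g_d, cfg.p_in, cfg.p_out), index=lncrnas, columns=diseases
    )

    sequences = {
        name: _group_sequence(rng_seq, int(g), cfg.seq_length) for name, g in zip(lncrnas, g_l)
    }

    # per-group ancestor chain anc_g_1 -> ... -> anc_g_depth -> disease_root,
    # shared by every disease of the group
    graph = nx.DiGraph()
    for g in range(cfg.n_groups):
        chain = [f"anc_g{g}_{level}" for level in range(1, cfg.dag_depth + 1)]
        for child, parent in zip(chain, chain[1:]):
            graph.add_edge(child, parent)
        graph.add_edge(chain[-1], "disease_root")
    for name, g in zip(diseases, g_d):
        graph.add_edge(name, f"anc_g{int(g)}_1")
    all_dags = _dags_from_graph(graph)
    dags = {d: all_dags[d] for d in diseases}

    same = g_m[:, None] == g_m[None, :]
    fs_vals = np.where(same, cfg.fs_in, cfg.fs_out)
    np.fill_diagonal(fs_vals, 1.0)
    fs = pd.DataFrame(fs_vals, index=mirnas, columns=mirnas)

    dataset = Dataset(a=a, b=b, c=c, sequences=sequences, dags=dags, fs=fs)
    dataset.validate()
    groups = {
        **{name: int(g) for name, g in zip(mirnas, g_m)},
        **{name: int(g) for name, g in zip(diseases, g_d)},
        **{name: int(g) for name, g in zip(lncrnas, g_l)},
    }
    return dataset, groups


def write_bundle(dataset: Dataset, directory, force: bool = False) -> dict[str, Path]:
    """Write a dataset as the plain-text files the readers consume.

    Also writes an explicit entity index (name, role) so matrices round-trip
    even when an entity has no associations.  Refuses to overwrite an
    existing bundle unless ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / fname for key, fname in BUNDLE_FILES.items()}
    if not force:
        existing = [p.name for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"bundle files already exist in {directory} (use force=True): {existing}"
            )
    write_association_edgelist(dataset.a, paths["a"])
    write_association_edgelist(dataset.b, paths["b"])
    write_association_edgelist(dataset.c, paths["c"])
    write_fasta(dataset.sequences, paths["fasta"])
    write_dag_edges(dataset.dags, paths["dag"])
    write_named_matrix(dataset.fs, paths["fs"])
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for name in dataset.mirnas:
            fh.write(f"{name}\tmiRNA\n")
        for name in dataset.diseases:
            fh.write(f"{name}\tdisease\n")
        for name in dataset.lncrnas:
            fh.write(f"{name}\tlncRNA\n")
    return paths


def read_bundle(directory) -> Dataset:
    """Read a bundle written by :func:`write_bundle` back into a Dataset."""
    directory = Path(directory)
    paths = {key: directory / fname for key, fname in BUNDLE_FILES.items()}
    roles: dict[str, list[str]] = {"miRNA": [], "disease": [], "lncRNA": []}
    with open(paths["entities"], encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            name, role = line.split("\t")
            roles[role].append(name)
    mirnas, diseases, lncrnas = roles["miRNA"], roles["disease"], roles["lncRNA"]
    a = read_association_edgelist(paths["a"], rows=mirnas, cols=diseases)
    b = read_association_edgelist(paths["b"], rows=mirnas, cols=lncrnas)
    c = read_association_edgelist(paths["c"], rows=lncrnas, cols=diseases)
    sequences = read_fasta(paths["fasta"])
    all_dags = read_dag_edges(paths["dag"])
    dags = {d: all_dags[d] for d in diseases if d in all_dags}
    fs = read_named_matrix(paths["fs"])
    return align_dataset(a, b, c, sequences, dags, fs)
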