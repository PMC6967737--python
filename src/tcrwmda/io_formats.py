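"""Readers and writers for every external file the pipeline touches.

All tabular formats are plain TSV (tab-separated, no quoting, UTF-8,
``#``-prefixed comment lines skipped).  Matrices travel as pandas DataFrames
whose index/columns carry the entity names; associations are binary edge
lists; disease hierarchies are child→parent edge lists over MeSH-like terms.
Internal indexing is 0-based everywhere; files always use names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAG",
    "Dataset",
    "read_association_edgelist",
    "read_fasta",
    "read_dag_edges",
    "dag_from_mesh_tree_numbers",
    "read_named_matrix",
    "write_named_matrix",
    "write_association_edgelist",
    "write_dag_edges",
    "write_fasta",
    "align_dataset",
]

#: significant digits preserved by named-matrix round trips
_FLOAT_FMT = "%.12g"


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_edgelist(
    path,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a two-column TSV of (row entity, column entity) pairs.

    Returns a binary DataFrame with entry 1 iff the pair appears at least
    once (duplicates are idempotent).  When ``rows``/``cols`` are omitted the
    entity order is first appearance in the file; when provided, any name
    outside them raises with the offending line number.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    row_seen: dict[str, None] = {}
    col_seen: dict[str, None] = {}
    row_set = set(rows) if rows is not None else None
    col_set = set(cols) if cols is not None else None
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed line, expected two tab-separated names")
        r, c = parts
        if row_set is not None and r not in row_set:
            raise ValueError(f"{path}:{lineno}: unknown entity {r!r} not in the row index")
        if col_set is not None and c not in col_set:
            raise ValueError(f"{path}:{lineno}: unknown entity {c!r} not in the column index")
        row_seen.setdefault(r, None)
        col_seen.setdefault(c, None)
        pairs.append((r, c))
    row_index = pd.Index(list(rows) if rows is not None else list(row_seen), name="row")
    col_index = pd.Index(list(cols) if cols is not None else list(col_seen), name="col")
    if row_index.has_duplicates or col_index.has_duplicates:
        raise ValueError("entity indices must be unique")
    values = np.zeros((len(row_index), len(col_index)))
    rpos = {name: i for i, name in enumerate(row_index)}
    cpos = {name: j for j, name in enumerate(col_index)}
    for r, c in pairs:
        values[rpos[r], cpos[c]] = 1.0
    return pd.DataFrame(values, index=row_index, columns=col_index)


def write_association_edgelist(assoc: pd.DataFrame, path) -> None:
    """Write the positive entries of a binary matrix as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in assoc.index:
            for c in assoc.columns:
                if assoc.at[r, c] != 0:
                    fh.write(f"{r}\t{c}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name→sequence map.

    The name is the header token up to the first whitespace; sequences are
    uppercased but otherwise kept verbatim.  Duplicate headers and empty
    sequences are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate FASTA header {name!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {name!r} in {path}")
        sequences[name] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease's ancestor graph: the disease itself plus all terms reachable
    along child→parent edges, with the induced edges.

    ``graph`` is a DiGraph whose edges point child→parent and whose node set
    is exactly ``nodes`` (written T(D) in the semantic-similarity models).
    """

    root: str
    graph: nx.DiGraph = field(compare=False)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def children_of(self, term: str) -> list[str]:
        """Terms of this DAG whose parent (toward the hierarchy root) is ``term``."""
        return sorted(self.graph.predecessors(term))

    def __eq__(self, other) -> bool:  # structural equality, used by round-trip tests
        if not isinstance(other, DiseaseDAG):
            return NotImplemented
        return (
            self.root == other.root
            and set(self.graph.nodes) == set(other.graph.nodes)
            and set(self.graph.edges) == set(other.graph.edges)
        )

    def __hash__(self) -> int:
        return hash(self.root)


def _dags_from_graph(global_graph: nx.DiGraph) -> dict[str, DiseaseDAG]:
    try:
        cycle = nx.find_cycle(global_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"hierarchy contains a cycle: {pretty}")
    dags: dict[str, DiseaseDAG] = {}
    for node in global_graph.nodes:
        # edges point child -> parent, so ancestors are graph descendants
        ancestors = nx.descendants(global_graph, node)
        members = ancestors | {node}
        dags[node] = DiseaseDAG(root=node, graph=global_graph.subgraph(members).copy())
    return dags


def read_dag_edges(path) -> dict[str, DiseaseDAG]:
    """Read child<TAB>parent term edges and build one DAG per term present."""
    path = Path(path)
    graph = nx.DiGraph()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed line, expected child<TAB>parent")
        graph.add_edge(parts[0], parts[1])
    return _dags_from_graph(graph)


def _validate_tree_number(tn: str, path: Path, lineno: int) -> None:
    segments = tn.split(".")
    if not segments or any(not seg or not seg.isalnum() for seg in segments):
        raise ValueError(f"{path}:{lineno}: malformed tree number {tn!r}")


def dag_from_mesh_tree_numbers(path) -> dict[str, DiseaseDAG]:
    """Build disease DAGs from a disease<TAB>tree-number table.

    Ancestry follows dot truncation of tree numbers (C04.557 sits under C04);
    the parent of a term is the disease owning the longest proper dot-prefix
    present in the table.  A disease may carry several tree numbers; its DAG
    is the union of the ancestor chains.
    """
    path = Path(path)
    tn_owner: dict[str, str] = {}
    entries: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed line, expected disease<TAB>tree_number")
        disease, tn = parts
        _validate_tree_number(tn, path, lineno)
        entries.append((disease, tn))
        tn_owner.setdefault(tn, disease)
    graph = nx.DiGraph()
    for disease, tn in entries:
        graph.add_node(disease)
        segments = tn.split(".")
        for cut in range(len(segments) - 1, 0, -1):
            prefix = ".".join(segments[:cut])
            parent = tn_owner.get(prefix)
            if parent is not None and parent != disease:
                graph.add_edge(disease, parent)
                break
    return _dags_from_graph(graph)


def write_dag_edges(dags: Mapping[str, DiseaseDAG], path) -> None:
    """Write the union of all per-disease DAG edges as child<TAB>parent TSV."""
    edges: set[tuple[str, str]] = set()
    for dag in dags.values():
        edges.update(dag.graph.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(edges):
            fh.write(f"{child}\t{parent}\n")


def read_named_matrix(path) -> pd.DataFrame:
    """Read a TSV with a header row of column names and a first column of row names."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed matrix: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: ragged rows or missing cells in matrix")
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def write_named_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a named matrix as TSV, value-preserving to 12 significant digits."""
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


@dataclass
class Dataset:
    """One run's worth of inputs over consistent entity indices.

    a : miRNA × disease binary associations
    b : miRNA × lncRNA binary associations
    c : lncRNA × disease binary associations
    sequences : lncRNA name → nucleotide sequence
    dags : disease name → DiseaseDAG (absent = no semantic annotation)
    fs : precomputed miRNA functional-similarity matrix (MISIM-style)
    """

    a: pd.DataFrame
    b: pd.DataFrame
    c: pd.DataFrame
    sequences: dict[str, str]
    dags: dict[str, DiseaseDAG]
    fs: pd.DataFrame

    @property
    def mirnas(self) -> pd.Index:
        return self.a.index

    @property
    def diseases(self) -> pd.Index:
        return self.a.columns

    @property
    def lncrnas(self) -> pd.Index:
        return self.b.columns

    def validate(self) -> None:
        if not self.a.index.equals(self.b.index):
            raise ValueError("A and B must share the miRNA index")
        if not self.b.columns.equals(self.c.index):
            raise ValueError("B columns and C rows must share the lncRNA index")
        if not self.a.columns.equals(self.c.columns):
            raise ValueError("A and C must share the disease index")
        for m in (self.a, self.b, self.c):
            vals = m.to_numpy()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("association matrices must be binary")


def align_dataset(
    a: pd.DataFrame,
    b: pd.DataFrame,
    c: pd.DataFrame,
    sequences: Mapping[str, str],
    dags: Mapping[str, DiseaseDAG],
    fs: pd.DataFrame,
) -> Dataset:
    """Reindex B and C onto A's miRNA/disease indices and a shared lncRNA index.

    A's first-appearance order defines the miRNA and disease indices.  The
    lncRNA index is the union of B's columns and C's rows in first-appearance
    order.  Entities present in B or C but absent from A's indices are
    dropped with a logged warning, mirroring the usual filtering of auxiliary
    associations down to the entities of the primary matrix.
    """
    mirnas, diseases = a.index, a.columns
    lnc_names = list(dict.fromkeys(list(b.columns) + list(c.index)))
    lncrnas = pd.Index(lnc_names, name="lncRNA")

    dropped_m = sorted(set(b.index) - set(mirnas))
    dropped_d = sorted(set(c.columns) - set(diseases))
    if dropped_m:
        logger.warning("dropping %d miRNA(s) absent from A: %s", len(dropped_m), dropped_m[:5])
    if dropped_d:
        logger.warning("dropping %d disease(s) absent from A: %s", len(dropped_d), dropped_d[:5])

    b_aligned = b.reindex(index=mirnas, columns=lncrnas, fill_value=0.0).astype(float)
    c_aligned = c.reindex(index=lncrnas, columns=diseases, fill_value=0.0).astype(float)
    ds = Dataset(
        a=a.astype(float),
        b=b_aligned,
        c=c_aligned,
        sequences=dict(sequences),
        dags=dict(dags),
        fs=fs,
    )
    ds.validate()
    return ds
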