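"""Trees, count tables, and per-edge mass vectors.

The tree model is a rooted, edge-weighted tree stored as flat parent/length
arrays. An edge belongs to its child node, so the root carries no edge and
edge ids are simply non-root node ids. Every phylogenetic measure in this
package is a sum over edges of a function of the edge length and the fraction
of a sample's reads on the distal (away-from-root) side of the edge; this
module computes those per-edge masses in a single post-order pass.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "CountTable",
    "SampleCounts",
    "EdgeMassVector",
    "TreeParseError",
    "TableFormatError",
    "AlignmentError",
    "read_newick",
    "write_newick",
    "read_count_table",
    "align_tree_table",
    "compute_edge_masses",
    "reroot",
]

ROOT_PARENT = -1


class TreeParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, bad lengths, ...)."""


class TableFormatError(ValueError):
    """Malformed count table (non-integer cells, duplicate labels, ...)."""


class AlignmentError(ValueError):
    """Tree leaves and table rows disagree."""


class PhyloTree:
    """Rooted, edge-weighted tree with uniquely labeled tips.

    Parameters
    ----------
    parent:
        ``parent[v]`` is the parent node id of ``v``, or ``-1`` for the root.
    length:
        ``length[v]`` is the length of the edge above ``v`` (0.0 at the root).
    labels:
        Per-node label or ``None``. Tip labels must be unique and non-empty;
        internal labels are preserved but unused.
    """

    def __init__(self, parent: np.ndarray, length: np.ndarray, labels: list[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise ValueError("parent, length, labels must have equal size")
        roots = np.flatnonzero(self.parent == ROOT_PARENT)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        if not np.all(np.isfinite(self.length)):
            raise TreeParseError("non-finite branch length")
        if np.any(self.length < 0):
            raise TreeParseError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p != ROOT_PARENT:
                self.children[p].append(v)
        self._validate_connected()
        self._validate_tip_labels()
        self._postorder: np.ndarray | None = None

    # -- construction helpers -------------------------------------------------

    def _validate_connected(self) -> None:
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [self.root]
        while stack:
            v = stack.pop()
            if seen[v]:
                raise ValueError("cycle detected in tree")
            seen[v] = True
            stack.extend(self.children[v])
        if not seen.all():
            raise ValueError("tree is not connected")

    def _validate_tip_labels(self) -> None:
        seen: set[str] = set()
        for v in self.tip_ids():
            lab = self.labels[v]
            if lab is None or lab == "":
                raise TreeParseError(f"unlabeled tip node {v}")
            if lab in seen:
                raise TreeParseError(f"duplicate leaf label {lab!r}")
            seen.add(lab)

    # -- basic structure ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def edge_ids(self) -> np.ndarray:
        """Non-root node ids; the edge above each is 'its' edge."""
        return np.flatnonzero(self.parent != ROOT_PARENT)

    def tip_ids(self) -> list[int]:
        """Nodes of undirected degree 1 (stable under rerooting).

        A root with a single child counts as a tip so that rerooting at a
        leaf keeps that leaf addressable by label.
        """
        out = []
        for v in range(self.n_nodes):
            deg = len(self.children[v]) + (0 if v == self.root else 1)
            if deg <= 1:
                out.append(v)
        return out

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_ids()]

    def tip_index(self) -> dict[str, int]:
        return {self.labels[v]: v for v in self.tip_ids()}

    def postorder(self) -> np.ndarray:
        """Node ids in post-order (children before parents); cached."""
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def total_length(self) -> float:
        return float(self.length[self.edge_ids()].sum())

    def scale_lengths(self, c: float) -> "PhyloTree":
        t = PhyloTree(self.parent.copy(), self.length * c, list(self.labels))
        return t

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.tip_labels)} tips, {self.n_edges} edges>"


@dataclass
class SampleCounts:
    """One sample: leaf label -> non-negative integer count."""

    counts: dict[str, int]
    name: str = "sample"

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for leaf, c in self.counts.items():
            ci = int(c)
            if ci != c or ci < 0:
                raise TableFormatError(f"count for {leaf!r} must be a non-negative integer, got {c!r}")
            clean[str(leaf)] = ci
        self.counts = clean

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def nonzero(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if v > 0}

    def as_vector(self, order: Iterable[str]) -> np.ndarray:
        return np.array([self.counts.get(k, 0) for k in order], dtype=np.int64)


class CountTable:
    """Leaves-by-samples matrix of non-negative integer counts."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate row labels: {dups[:10]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups[:10]}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise TableFormatError("non-numeric cell in count table")
        if arr.size:
            frac = arr != np.floor(arr)
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise TableFormatError(
                    f"non-integer count {arr[r, c]!r} at row {data.index[r]!r}, column {data.columns[c]!r}"
                )
            neg = arr < 0
            if neg.any():
                r, c = np.argwhere(neg)[0]
                raise TableFormatError(
                    f"negative count at row {data.index[r]!r}, column {data.columns[c]!r}"
                )
        self.data = data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, sample_id: str) -> SampleCounts:
        col = self.data[sample_id]
        return SampleCounts(dict(zip(self.data.index, col.astype(int))), name=sample_id)

    def samples(self) -> Iterable[SampleCounts]:
        for sid in self.sample_ids:
            yield self.sample(sid)

    def totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, sep="\t", index_label="leaf")

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class EdgeMassVector:
    """Per-edge distal counts and fractions for one sample.

    Arrays are indexed by node id; the root entry holds the whole-sample
    total but is not an edge.
    """

    tree: PhyloTree
    d: np.ndarray  # distal read counts, int64, indexed by node id
    n: int  # sample total

    @property
    def fractions(self) -> np.ndarray:
        return self.d / self.n

    def edge_counts(self) -> np.ndarray:
        return self.d[self.tree.edge_ids()]

    def edge_fractions(self) -> np.ndarray:
        return self.d[self.tree.edge_ids()] / self.n

    def edge_lengths(self) -> np.ndarray:
        return self.tree.length[self.tree.edge_ids()]


# -- Newick I/O ---------------------------------------------------------------


def read_newick(text: str) -> PhyloTree:
    """Parse a single Newick tree into a :class:`PhyloTree`.

    Quoted labels are supported; internal node labels are preserved but
    unused. Missing branch lengths default to 0.0 with a warning. The tree
    is rooted at the outermost Newick node.
    """
    if ";" not in text:
        raise TreeParseError("Newick text must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"Newick parse error: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, ROOT_PARENT, dtype=np.int64)
    length = np.zeros(n, dtype=float)
    labels: list[str | None] = [None] * n
    missing = 0
    for i, nd in enumerate(nodes):
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                missing += 1
                length[i] = 0.0
            else:
                if nd.edge.length < 0:
                    raise TreeParseError(
                        f"negative branch length {nd.edge.length} on edge above {labels[i] or i}"
                    )
                length[i] = float(nd.edge.length)
    if missing:
        warnings.warn(f"{missing} missing branch length(s) set to 0.0", UserWarning)
    if n == 1:
        warnings.warn("degenerate single-leaf tree", UserWarning)
    return PhyloTree(parent, length, labels)


def _quote_label(lab: str) -> str:
    specials = set("()[]':;,= \t\n")
    if any(ch in specials for ch in lab):
        return "'" + lab.replace("'", "''") + "'"
    return lab


def write_newick(tree: PhyloTree, include_lengths: bool = True) -> str:
    """Serialize a :class:`PhyloTree` back to Newick."""

    def render(v: int) -> str:
        kids = tree.children[v]
        if kids:
            body = "(" + ",".join(render(k) for k in kids) + ")"
        else:
            body = ""
        lab = tree.labels[v]
        s = body + (_quote_label(lab) if lab else "")
        if v != tree.root and include_lengths:
            s += f":{tree.length[v]:.12g}"
        return s

    return render(tree.root) + ";"


# -- Count-table I/O ----------------------------------------------------------


def read_count_table(path, format: str = "auto") -> CountTable:
    """Read a count table from TSV or BIOM-JSON v1.0.

    TSV: first column = leaf label, header row = sample ids, integer cells.
    BIOM: JSON v1.0, dense or sparse; sparse zeros materialize as 0.
    """
    fmt = format
    spath = str(path)
    if fmt == "auto":
        fmt = "biom-json" if spath.endswith((".biom", ".json")) else "tsv"
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_tsv(path) -> CountTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:
        raise TableFormatError(f"cannot read TSV table {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableFormatError(f"non-numeric cell at row {row!r}, column {col!r}")
    return CountTable(df)


def _read_biom_json(path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        nrow, ncol = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise TableFormatError(f"missing BIOM field {exc}") from exc
    if (len(rows), len(cols)) != (nrow, ncol):
        raise TableFormatError("BIOM shape does not match row/column metadata")
    mat = np.zeros((nrow, ncol), dtype=float)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    else:
        raise TableFormatError(f"unknown BIOM matrix_type {mtype!r}")
    return CountTable(pd.DataFrame(mat, index=rows, columns=cols))


def write_biom_json(table: CountTable, path, table_id: str = "phylodiv") -> None:
    data = []
    arr = table.data.to_numpy()
    for r, c in zip(*np.nonzero(arr)):
        data.append([int(r), int(c), int(arr[r, c])])
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "phylodiv",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(table.leaf_labels), len(table.sample_ids)],
        "rows": [{"id": r, "metadata": None} for r in table.leaf_labels],
        "columns": [{"id": c, "metadata": None} for c in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# -- alignment and edge masses ------------------------------------------------


def align_tree_table(tree: PhyloTree, table: CountTable, mode: str = "strict") -> CountTable:
    """Reconcile table rows with tree leaves.

    strict: row labels and tree leaves must coincide exactly.
    intersect: drop rows not on the tree (with a warning); tree leaves with
    no row get implicit count 0.
    """
    leaves = set(tree.tip_labels)
    rows = set(table.leaf_labels)
    if mode == "strict":
        extra = sorted(rows - leaves)
        missing = sorted(leaves - rows)
        if extra or missing:
            raise AlignmentError(
                "tree/table mismatch: "
                f"rows not on tree {extra[:10]}, leaves without rows {missing[:10]}"
            )
        return table
    if mode == "intersect":
        extra = sorted(rows - leaves)
        if extra:
            warnings.warn(f"dropping {len(extra)} table row(s) not on the tree", UserWarning)
        keep = [r for r in table.leaf_labels if r in leaves]
        return CountTable(table.data.loc[keep])
    raise ValueError(f"unknown alignment mode {mode!r}")


def compute_edge_masses(tree: PhyloTree, sample: SampleCounts | Mapping[str, int]) -> EdgeMassVector:
    """Accumulate distal read counts d_i for every edge in one post-order pass."""
    if not isinstance(sample, SampleCounts):
        sample = SampleCounts(dict(sample))
    n = sample.n
    if n == 0:
        raise ValueError("empty sample")
    tips = tree.tip_index()
    unknown = set(sample.nonzero()) - set(tips)
    if unknown:
        raise AlignmentError(f"sample has reads at labels not on the tree: {sorted(unknown)[:10]}")
    d = np.zeros(tree.n_nodes, dtype=np.int64)
    for lab, c in sample.counts.items():
        if lab in tips:
            d[tips[lab]] += c
    for v in tree.postorder():
        p = tree.parent[v]
        if p != ROOT_PARENT:
            d[p] += d[v]
    return EdgeMassVector(tree=tree, d=d, n=n)


def reroot(tree: PhyloTree, node: int) -> PhyloTree:
    """Return the same undirected tree re-oriented from a new root node."""
    if not (0 <= node < tree.n_nodes):
        raise ValueError(f"unknown node id {node}")
    if node == tree.root:
        return PhyloTree(tree.parent.copy(), tree.length.copy(), list(tree.labels))
    # undirected adjacency with the length of each undirected edge
    adj: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.edge_ids():
        p = int(tree.parent[v])
        adj[v].append((p, float(tree.length[v])))
        adj[p].append((v, float(tree.length[v])))
    parent = np.full(tree.n_nodes, ROOT_PARENT, dtype=np.int64)
    length = np.zeros(tree.n_nodes, dtype=float)
    seen = np.zeros(tree.n_nodes, dtype=bool)
    stack = [node]
    seen[node] = True
    while stack:
        v = stack.pop()
        for w, lw in adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[w] = v
                length[w] = lw
                stack.append(w)
    return PhyloTree(parent, length, list(tree.labels))
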