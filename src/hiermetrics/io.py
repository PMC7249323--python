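"""Readers and writers for the plain-text formats the tools exchange.

Labels are two-column CSV/TSV (``cell_id,label``); weight matrices are
CSV with type names as both header and first column; trees are Newick
with branch lengths (or a merge-table CSV mirroring agglomerative
clustering output); expression is a dense genes x cells CSV/TSV or a
MatrixMarket ``.mtx`` with gene/barcode sidecar files.  Every writer
round-trips through its reader.
"""

from __future__ import annotations

import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .partitions import PartitionLabels
from .structured_entropy import ReferenceTree
from .weight_estimation import ExpressionMatrix
from .weighted_rand import WeightMatrices

__all__ = [
    "read_labels",
    "write_labels",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_weights",
    "write_weights",
    "read_tree",
    "write_tree",
    "read_tree_merge_table",
    "read_expression",
    "write_expression",
]


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_labels(path, positional: bool = False) -> PartitionLabels:
    """Read a label table.

    Default schema: header ``cell_id,label``.  With ``positional=True``
    a single label column (optionally headed ``label``) is accepted and
    cells are matched by row position via generated ids ``cell1..n`` —
    only safe when every file being compared lists cells in the same
    order.
    """
    path = pathlib.Path(path)
    sep = _sep_for(path)
    if positional:
        raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if raw and raw[0].lower() == "label":
            raw = raw[1:]
        if len(raw) < 2:
            raise SchemaError(f"{path}: fewer than 2 labels")
        return PartitionLabels(
            tuple(f"cell{i + 1}" for i in range(len(raw))), tuple(raw)
        )
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: cannot parse as {sep!r}-separated table: {exc}")
    required = ["cell_id", "label"]
    if list(df.columns[:2]) != required:
        raise SchemaError(
            f"{path}: expected header 'cell_id{sep}label', got "
            f"{list(df.columns)[:2]}"
        )
    bad = df.index[df[required].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(
            f"{path}: empty cell_id/label at data line(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    return PartitionLabels(tuple(df["cell_id"]), tuple(df["label"]))


def write_labels(path, part: PartitionLabels) -> None:
    pd.DataFrame({"cell_id": part.cell_ids, "label": part.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_weight_matrix(path):
    """Read one J x J weight matrix CSV; returns ``(type_labels, matrix)``.

    The header row and first column must carry the same type names;
    missing entries are an error (no silent defaults).
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    rows = [str(v) for v in df.index]
    cols = [str(v) for v in df.columns]
    if set(rows) != set(cols):
        raise SchemaError(
            f"{path}: row and column type names differ: "
            f"rows-only {sorted(set(rows) - set(cols))[:5]}, "
            f"cols-only {sorted(set(cols) - set(rows))[:5]}"
        )
    df.columns = cols
    df = df[rows]  # align column order to row order
    if df.isna().any().any():
        holes = [
            (rows[i], rows[j]) for i, j in zip(*np.where(df.isna().to_numpy()))
        ]
        raise SchemaError(f"{path}: missing weight entries at {holes[:5]}")
    return tuple(rows), df.to_numpy(dtype=float)


def write_weight_matrix(path, type_labels: Sequence, matrix: np.ndarray) -> None:
    labels = [str(t) for t in type_labels]
    pd.DataFrame(np.asarray(matrix, dtype=float), index=labels, columns=labels).to_csv(
        path, sep=_sep_for(path)
    )


def read_weights(w1_path, w0_path, canonical: bool = True) -> WeightMatrices:
    """Read a W1/W0 pair; the two files must name the same types."""
    labels1, w1 = read_weight_matrix(w1_path)
    labels0, w0 = read_weight_matrix(w0_path)
    if set(labels1) != set(labels0):
        raise SchemaError(
            "W1 and W0 name different types: "
            f"{sorted(set(labels1) ^ set(labels0))[:5]}"
        )
    order = [labels0.index(t) for t in labels1]
    return WeightMatrices(
        w1=w1, w0=w0[np.ix_(order, order)], type_labels=labels1, canonical=canonical
    )


def write_weights(w1_path, w0_path, weights: WeightMatrices) -> None:
    write_weight_matrix(w1_path, weights.type_labels, weights.w1)
    write_weight_matrix(w0_path, weights.type_labels, weights.w0)


def read_tree(path, ultrametric_tol: float = 1e-6) -> ReferenceTree:
    """Read a Newick tree with branch lengths."""
    text = pathlib.Path(path).read_text()
    return ReferenceTree.from_newick(text, ultrametric_tol=ultrametric_tol)


def write_tree(path, tree: ReferenceTree) -> None:
    pathlib.Path(path).write_text(tree.to_newick() + "\n")


def read_tree_merge_table(path) -> ReferenceTree:
    """Read a tree as a merge table: CSV with columns ``step``,
    ``height`` and ``members``, where ``members`` lists (``|``-joined)
    all leaf types of the cluster formed at that step — the shape of
    agglomerative-clustering output.  A step joining m sub-clusters
    becomes m-1 binary merges at the same height.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("step", "height", "members"):
        if col not in df.columns:
            raise SchemaError(f"{path}: merge table is missing column {col!r}")
    df = df.sort_values("step", key=lambda s: s.astype(int))

    leaf_names: list = []
    for members in df["members"]:
        for m in str(members).split("|"):
            if m and m not in leaf_names:
                leaf_names.append(m)
    index = {name: k for k, name in enumerate(leaf_names)}
    clusters = {frozenset([index[n]]): index[n] for n in leaf_names}
    children, heights = [], []
    J = len(leaf_names)
    for _, row in df.iterrows():
        members = frozenset(index[m] for m in str(row["members"]).split("|") if m)
        parts = [c for c in clusters if c <= members]
        if frozenset().union(*parts) != members or len(parts) < 2:
            raise SchemaError(
                f"{path}: step {row['step']} members are not a union of "
                "existing clusters"
            )
        h = float(row["height"])
        parts.sort(key=min)
        acc = parts[0]
        for other in parts[1:]:
            children.append((clusters.pop(acc), clusters.pop(other)))
            heights.append(h)
            node = J + len(children) - 1
            acc = acc | other
            clusters[acc] = node
    if len(clusters) != 1:
        raise SchemaError(f"{path}: merge table does not join all types")
    return ReferenceTree(tuple(leaf_names), np.array(children), np.array(heights))


def _sidecar(path: pathlib.Path, kind: str) -> pathlib.Path:
    return path.with_suffix(f".{kind}.txt")


def read_expression(
    path, genes_file=None, cells_file=None
) -> ExpressionMatrix:
    """Read a genes x cells matrix.

    ``.mtx`` (MatrixMarket) input needs gene and cell id sidecar files,
    one id per line; by default ``<stem>.genes.txt`` and
    ``<stem>.barcodes.txt`` next to the matrix.  Anything else is read
    as a dense CSV/TSV with gene ids in the first column and cell ids in
    the header.
    """
    path = pathlib.Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        genes_file = pathlib.Path(genes_file) if genes_file else _sidecar(path, "genes")
        cells_file = (
            pathlib.Path(cells_file) if cells_file else _sidecar(path, "barcodes")
        )
        for f, what in ((genes_file, "gene"), (cells_file, "cell")):
            if not f.exists():
                raise SchemaError(
                    f"MatrixMarket input needs a {what}-id sidecar file; "
                    f"{f} not found"
                )
        values = np.asarray(mmread(path).todense(), dtype=float)
        gene_ids = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
        cell_ids = [ln.strip() for ln in cells_file.read_text().splitlines() if ln.strip()]
        return ExpressionMatrix(values, tuple(gene_ids), tuple(cell_ids))
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        tuple(str(g) for g in df.index),
        tuple(str(c) for c in df.columns),
    )


def write_expression(path, expr: ExpressionMatrix) -> None:
    """Write expression as dense CSV/TSV, or as ``.mtx`` plus
    ``<stem>.genes.txt`` / ``<stem>.barcodes.txt`` sidecars."""
    path = pathlib.Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(expr.values))
        _sidecar(path, "genes").write_text("\n".join(expr.gene_ids) + "\n")
        _sidecar(path, "barcodes").write_text("\n".join(expr.cell_ids) + "\n")
        return
    pd.DataFrame(
        expr.values, index=list(expr.gene_ids), columns=list(expr.cell_ids)
    ).to_csv(path, sep=_sep_for(path), index_label="gene_id")
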