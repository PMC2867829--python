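"""File formats and the in-memory expression-matrix container.

Native dialect is TSV (gene annotations commonly contain commas), UTF-8,
LF line endings, ``.`` decimal separator.  All writers are deterministic:
stable row ordering and fixed 9-significant-digit float formatting, so
re-running a pipeline with the same inputs produces byte-identical files.
Missing values are not representable; the pipeline assumes complete
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_results_table",
    "write_graph",
    "read_graphml",
]

#: significant digits used by every table writer
FLOAT_DIGITS = 9


class FormatError(ValueError):
    """A file violated the matrix / sample-sheet / graph format contract."""


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return format(float(x), f".{FLOAT_DIGITS}g")
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    return str(x)


@dataclass
class ExpressionMatrix:
    """A genes-by-samples log2 signal matrix with a time-group design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample, log2 scale.
    design
        DataFrame indexed by sample id with columns ``group`` and
        ``replicate``.  Row order defines the sample order.
    group_order
        Time groups in temporal order.  Defaults to first-appearance order
        in ``design``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated gene id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicated sample id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(
                f"sample {missing[0]!r} in matrix missing from sample sheet"
            )
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        # align design to the matrix's sample order
        self.design = self.design.loc[list(self.values.columns)]
        if not self.group_order:
            self.group_order = list(dict.fromkeys(self.design["group"]))

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        """Sample -> time-group label, in sample order."""
        return self.design["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.design.index[self.design["group"] == group])

    def require_replicated(self, min_replicates: int = 2) -> None:
        """Raise unless every group has at least ``min_replicates`` samples."""
        counts = self.groups.value_counts()
        for g in self.group_order:
            if counts.get(g, 0) < min_replicates:
                raise FormatError(
                    f"group {g!r} has {counts.get(g, 0)} replicates; "
                    f"variance-based tests need >= {min_replicates}"
                )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)].copy(),
            self.design.copy(),
            list(self.group_order),
        )


def read_expression_matrix(matrix_path, sheet_path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus sample sheet.

    The matrix has a header row of sample ids and a first column of gene
    ids; the sheet has columns ``sample_id``, ``group``, ``replicate``.
    Sample order in the matrix is preserved; group order follows the
    sheet's declaration order.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell {cell!r} at row {i + 2}, "
                        f"column {j + 2} (gene {raw.index[i]!r}, sample {col!r}) "
                        f"of {matrix_path}"
                    ) from None
        raise  # pragma: no cover - unreachable: a bad cell was found above
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, "
            f"got {list(sheet.columns)}"
        )
    design = sheet.set_index("sample_id")[["group", "replicate"]]
    if not design.index.is_unique:
        dup = design.index[design.index.duplicated()][0]
        raise FormatError(f"duplicated sample id in sheet: {dup!r}")
    group_order = list(dict.fromkeys(sheet["group"]))
    return ExpressionMatrix(values, design, group_order)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, sheet_path) -> None:
    """Write matrix + sheet in the format read by :func:`read_expression_matrix`."""
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        arr = matrix.values.to_numpy()
        for gene, row in zip(matrix.gene_ids, arr):
            fh.write(str(gene) + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")
    with open(sheet_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\treplicate\n")
        for sample, row in matrix.design.iterrows():
            fh.write(f"{sample}\t{row['group']}\t{row['replicate']}\n")


def write_truth_labels(truth: pd.Series, path) -> None:
    """Write planted truth labels as a two-column TSV (gene, label)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tlabel\n")
        for gene, label in truth.items():
            fh.write(f"{gene}\t{label}\n")


def write_results_table(records, path) -> None:
    """Write a per-gene result set as a deterministic TSV.

    ``records`` is a DataFrame (or a list of dicts sharing a schema).
    Floats are printed with 9 significant digits.  When the schema carries
    node-topology columns (``core`` and ``degree``) rows are ordered
    descending by core number, then descending degree, then gene id — the
    conventional ordering of hub-gene topology reports.  An empty record
    set yields a header-only file.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    df = records.copy()
    if {"core", "degree"}.issubset(df.columns):
        id_col = df.columns[0]
        df = df.sort_values(
            ["core", "degree", id_col], ascending=[False, False, True], kind="mergesort"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Serialize a co-expression graph.

    ``graphml`` carries per-node ``degree`` / ``clustering`` / ``core``
    attributes when present; ``edge-list`` is ``geneA<TAB>geneB<TAB>r``
    with ``geneA < geneB`` lexicographically and rows sorted.
    """
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge-list":
        rows = []
        for u, v, data in graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            rows.append((a, b, data.get("weight", float("nan"))))
        rows.sort(key=lambda t: (t[0], t[1]))
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for a, b, r in rows:
                fh.write(f"{a}\t{b}\t{_fmt(float(r))}\n")
    else:
        raise FormatError(f"unsupported graph format: {format!r}")


def read_graphml(path) -> nx.Graph:
    """Read back a GraphML file written by :func:`write_graph`."""
    return nx.read_graphml(path)
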