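"""Core data containers and file round-trip for OTU-table analyses.

In-memory orientation is always samples x OTUs; the BIOM-style TSV dialect
(rows = OTUs, ``#OTU ID`` header, optional trailing taxonomy column) is
transposed on read. All counts are validated as non-negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "DistanceMatrix",
    "OtuTableParseError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_tree",
    "rarefy",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_network",
    "read_network",
]

METADATA_COLUMNS = ("sample_id", "group", "subject", "timepoint", "housing")


class OtuTableParseError(ValueError):
    """Raised when an OTU table file violates the count-matrix contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with identifiers and optional taxonomy.

    Parameters
    ----------
    sample_ids, otu_ids
        Unique row / column labels.
    counts
        Non-negative matrix, shape ``(n_samples, n_otus)``. Integral values
        are required on construction from files; float matrices are accepted
        for averaged (rarefied) views.
    taxonomy
        Optional mapping ``otu_id -> lineage string``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.otu_ids)})"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def proportions(self) -> np.ndarray:
        """Row-normalised relative abundances; errors on all-zero samples."""
        totals = self.counts.sum(axis=1, dtype=float)
        zero = [s for s, t in zip(self.sample_ids, totals) if t == 0]
        if zero:
            raise ValueError(f"samples with zero total counts: {zero}")
        return self.counts / totals[:, None]

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx], self.taxonomy)

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx], tax)


@dataclass
class SampleMetadata:
    """Per-sample design table: group, subject, timepoint (day) and housing."""

    table: pd.DataFrame
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        ids = self.table["sample_id"].astype(str)
        if ids.duplicated().any():
            raise ValueError(f"duplicate sample ids: {sorted(ids[ids.duplicated()])}")
        self.table = self.table.copy()
        self.table["sample_id"] = ids
        self.table["timepoint"] = self.table["timepoint"].astype(int)
        self.table = self.table.set_index("sample_id", drop=False)
        if not self.groups:
            self.groups = tuple(sorted(self.table["group"].astype(str).unique()))
        else:
            bad = set(self.table["group"]) - set(self.groups)
            if bad:
                raise ValueError(f"group labels outside the declared set: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def align_to(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].reset_index(drop=True), self.groups)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape}, expected ({n},{n})")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        _check_unique(self.sample_ids, "sample")
        self.values = (self.values + self.values.T) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_count(token: str, line_no: int, col: int, path) -> int:
    try:
        value = float(token)
    except ValueError:
        raise OtuTableParseError(
            f"{path}: non-numeric count {token!r} at line {line_no}, column {col}"
        ) from None
    if value < 0:
        raise OtuTableParseError(
            f"{path}: negative count {token!r} at line {line_no}, column {col}"
        )
    if value != int(value):
        raise OtuTableParseError(
            f"{path}: non-integral count {token!r} at line {line_no}, column {col}"
        )
    return int(value)


def read_otu_table(path, dialect: str = "plain_tsv") -> OtuTable:
    """Read a tab-separated OTU table.

    ``plain_tsv``: rows are samples, header row holds OTU ids.
    ``biom_tsv``: rows are OTUs, header starts with ``#OTU ID`` (a leading
    comment line is tolerated), an optional trailing ``taxonomy`` column is
    captured; the matrix is transposed to samples x OTUs on read.
    """
    if dialect not in ("plain_tsv", "biom_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise OtuTableParseError(f"{path}: empty file")

    if dialect == "plain_tsv":
        header = lines[0].split("\t")
        if len(header) < 2:
            raise OtuTableParseError(f"{path}: malformed header (need id column + OTUs)")
        otu_ids = header[1:]
        sample_ids, rows = [], []
        for line_no, line in enumerate(lines[1:], start=2):
            parts = line.split("\t")
            if len(parts) != len(header):
                raise OtuTableParseError(
                    f"{path}: line {line_no} has {len(parts)} fields, expected {len(header)}"
                )
            sample_ids.append(parts[0])
            rows.append([_parse_count(t, line_no, c + 2, path) for c, t in enumerate(parts[1:])])
        try:
            return OtuTable(sample_ids, otu_ids, np.array(rows, dtype=np.int64))
        except ValueError as exc:
            raise OtuTableParseError(f"{path}: {exc}") from None

    # biom_tsv
    start = 0
    if lines[0].startswith("#") and not lines[0].startswith("#OTU ID"):
        start = 1
    header = lines[start].split("\t")
    if not header[0].startswith("#OTU ID"):
        raise OtuTableParseError(f"{path}: biom_tsv header must start with '#OTU ID'")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else len(header)]
    otu_ids, cols, taxonomy = [], [], {}
    for line_no, line in enumerate(lines[start + 1 :], start=start + 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise OtuTableParseError(
                f"{path}: line {line_no} has {len(parts)} fields, expected {len(header)}"
            )
        otu_ids.append(parts[0])
        stop = -1 if has_tax else len(parts)
        cols.append([_parse_count(t, line_no, c + 2, path) for c, t in enumerate(parts[1:stop])])
        if has_tax:
            taxonomy[parts[0]] = parts[-1]
    try:
        return OtuTable(
            sample_ids, otu_ids, np.array(cols, dtype=np.int64).T, taxonomy or None
        )
    except ValueError as exc:
        raise OtuTableParseError(f"{path}: {exc}") from None


def write_otu_table(table: OtuTable, path, dialect: str = "plain_tsv") -> None:
    if dialect == "plain_tsv":
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(table.otu_ids) + "\n")
            for sid, row in zip(table.sample_ids, table.counts):
                fh.write(sid + "\t" + "\t".join(_fmt_count(v) for v in row) + "\n")
    elif dialect == "biom_tsv":
        has_tax = table.taxonomy is not None
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids))
            fh.write("\ttaxonomy\n" if has_tax else "\n")
            for j, oid in enumerate(table.otu_ids):
                fh.write(oid + "\t" + "\t".join(_fmt_count(v) for v in table.counts[:, j]))
                fh.write(f"\t{table.taxonomy.get(oid, '')}\n" if has_tax else "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _fmt_count(v) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def read_metadata(path, groups: tuple[str, ...] = ()) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str})
    return SampleMetadata(df, groups)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.reset_index(drop=True)[list(METADATA_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )


def read_tree(path):
    """Read a rooted newick tree (leaf labels = OTU ids, branch lengths >= 0)."""
    from skbio import TreeNode

    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    names = [t.name for t in tree.tips()]
    _check_unique(names, "leaf")
    return tree


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(map(str, df.index)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")


def write_network(net, path, format: str = "edge_tsv") -> None:
    """Write a correlation network as an edge-list TSV or GraphML."""
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tR\tp\n")
            for i, j, r, p in net.edges:
                fh.write(f"{i}\t{j}\t{r:.17g}\t{p:.17g}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for i, j, r, p in net.edges:
            g.add_edge(i, j, R=float(r), p=float(p))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv", nodes=None):
    """Round-trip counterpart of :func:`write_network`."""
    from .network import CorrelationNetwork

    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        edges = [
            (r.source, r.target, float(r.R), float(r.p)) for r in df.itertuples(index=False)
        ]
        node_list = list(nodes) if nodes is not None else sorted(
            {e[0] for e in edges} | {e[1] for e in edges}
        )
    elif format == "graphml":
        g = nx.read_graphml(path)
        edges = [(u, v, float(d["R"]), float(d["p"])) for u, v, d in g.edges(data=True)]
        node_list = list(g.nodes)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return CorrelationNetwork(nodes=node_list, edges=edges)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(
    table: OtuTable,
    depth: int,
    n_perm: int = 1000,
    seed: int = 0,
    on_shallow: str = "drop",
    return_permutations: bool = False,
):
    """Rarefy every sample to ``depth`` reads without replacement.

    Each of ``n_perm`` permutations subsamples each retained sample to exactly
    ``depth`` reads (multivariate hypergeometric draw, i.e. QIIME-style
    subsampling without replacement); the returned table holds the mean count
    across permutations, which need not be integral. Permutation ``k`` uses
    RNG seed ``seed + k``.

    Samples whose total is below ``depth`` are dropped (``on_shallow='drop'``)
    or raise (``'error'``). Samples exactly at ``depth`` pass through unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if on_shallow not in ("drop", "error"):
        raise ValueError(f"unknown on_shallow policy {on_shallow!r}")

    totals = table.counts.sum(axis=1)
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow and on_shallow == "error":
        raise ValueError(f"samples below depth {depth}: {shallow}")
    keep = [i for i, t in enumerate(totals) if t >= depth]
    if not keep:
        raise ValueError(f"no samples reach depth {depth}")
    counts = table.counts[keep]
    sample_ids = [table.sample_ids[i] for i in keep]

    acc = np.zeros(counts.shape, dtype=float)
    perms = []
    for k in range(n_perm):
        rng = np.random.default_rng(seed + k)
        perm = np.empty_like(counts)
        for i, row in enumerate(counts):
            if row.sum() == depth:
                perm[i] = row
            else:
                perm[i] = rng.multivariate_hypergeometric(row, depth)
        acc += perm
        if return_permutations:
            perms.append(OtuTable(sample_ids, list(table.otu_ids), perm, table.taxonomy))
    averaged = OtuTable(sample_ids, list(table.otu_ids), acc / n_perm, table.taxonomy)
    return (averaged, perms) if return_permutations else averaged
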