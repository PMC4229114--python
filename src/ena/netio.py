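"""Core data containers and plain-text I/O.

Three containers circulate through the package:

``ExpressionMatrix``
    A genes x samples real-valued matrix with row (gene) and column
    (sample) labels, as dumped by common microarray / RNA-seq pipelines.

``WeightedNetwork``
    An undirected weighted graph over a gene set, stored as a symmetric
    adjacency matrix of confidence scores.  A larger absolute score means
    a stronger inferred interaction; an exact zero means "no interaction".
    The diagonal is identically zero and is never ranked or evaluated.

``TrueNetwork``
    An unweighted gold-standard topology (set of undirected edges) used
    to simulate data and to score predictions.

File formats are deliberately plain: tab-separated matrices with labels,
and 2/3-column edge lists.  ``read_network`` auto-detects edge-list vs.
labelled square-matrix layout from the header shape.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "WeightedNetwork",
    "TrueNetwork",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_truth",
    "write_truth",
]

#: tolerance for accepting a nearly-symmetric square matrix on input
SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """A container invariant or an input contract was violated."""


class ParseError(ValueError):
    """A file could not be parsed into the requested container."""


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(x) for x in ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Labelled genes x samples expression matrix (arbitrary units)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene ids"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample ids"))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression values must all be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` (given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"unknown genes: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[rows])

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            self.gene_ids,
            tuple(self.sample_ids[i] for i in idx),
            self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric weighted adjacency over an ordered gene set."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene ids"))
        p = len(self.gene_ids)
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (p, p):
            raise ValidationError(f"scores shape {s.shape} does not match {p} genes")
        if not np.all(np.isfinite(s)):
            raise ValidationError("network scores must all be finite")
        asym = np.max(np.abs(s - s.T)) if p else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"adjacency is asymmetric (max |s-s'| = {asym:.3g})")
        if asym > 0:
            s = (s + s.T) / 2.0  # absorb printing round-off
        s = s.copy()
        np.fill_diagonal(s, 0.0)
        s.setflags(write=False)
        object.__setattr__(self, "scores", s)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        p = self.n_genes
        return p * (p - 1) // 2

    def tri_values(self) -> np.ndarray:
        """Scores of the N(N-1)/2 unordered pairs, row-major lower triangle."""
        i, j = np.tril_indices(self.n_genes, k=-1)
        return self.scores[i, j]

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered gene pairs in the same order as :meth:`tri_values`."""
        i, j = np.tril_indices(self.n_genes, k=-1)
        return [(self.gene_ids[b], self.gene_ids[a]) for a, b in zip(i, j)]


@dataclass(frozen=True)
class TrueNetwork:
    """Unweighted undirected gold-standard topology."""

    gene_ids: tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene ids"))
        known = set(self.gene_ids)
        norm = set()
        for e in self.edges:
            a, b = e
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r}")
            if a not in known or b not in known:
                raise ValidationError(f"edge endpoint not in gene set: {e!r}")
            norm.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Boolean symmetric adjacency in gene order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        a = np.zeros((self.n_genes, self.n_genes), dtype=bool)
        for u, v in self.edges:
            a[index[u], index[v]] = a[index[v], index[u]] = True
        return a

    def tri_labels(self) -> np.ndarray:
        """Pair membership labels in lower-triangle order."""
        a = self.adjacency()
        i, j = np.tril_indices(self.n_genes, k=-1)
        return a[i, j]


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a labelled genes x samples matrix (first row = sample ids,
    first column = gene ids)."""
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"expression file {path} has no sample columns")
    values = np.empty(df.shape, dtype=float)
    for ci, col in enumerate(df.columns):
        for ri, cell in enumerate(df[col]):
            try:
                values[ri, ci] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {cell!r} at gene {df.index[ri]!r}, "
                    f"sample {col!r} in {path}"
                ) from None
    if not np.all(np.isfinite(values)):
        ri, ci = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"non-finite cell at gene {df.index[ri]!r}, sample {df.columns[ci]!r} in {path}"
        )
    return ExpressionMatrix(tuple(df.index), tuple(df.columns), values)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=delimiter, index_label="")


# ---------------------------------------------------------------------------
# network I/O


def _read_table(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read network file {path}: {exc}") from exc


def _looks_like_matrix(raw: pd.DataFrame) -> bool:
    if raw.shape[0] != raw.shape[1] or raw.shape[0] < 2:
        return False
    header = [str(x) for x in raw.iloc[0, 1:]]
    rownames = [str(x) for x in raw.iloc[1:, 0]]
    return header == rownames


def read_network(path, gene_ids=None, delimiter: str = "\t") -> WeightedNetwork:
    """Read a weighted network from a 3-column edge list or a labelled
    square matrix (layout auto-detected from the header shape).

    When ``gene_ids`` is given the result has exactly that vertex set, in
    that order; genes in the file outside it are an error.
    """
    raw = _read_table(path, delimiter)
    if _looks_like_matrix(raw):
        labels = [str(x) for x in raw.iloc[0, 1:]]
        try:
            vals = raw.iloc[1:, 1:].astype(float).to_numpy()
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in matrix file {path}: {exc}") from exc
        net = WeightedNetwork(tuple(labels), vals)
        if gene_ids is not None:
            net = _reindex(net, gene_ids)
        return net
    if raw.shape[1] != 3:
        raise ParseError(
            f"{path}: expected a 3-column edge list or a labelled square matrix, "
            f"got shape {raw.shape}"
        )
    body = raw.iloc[1:]  # first row is the header
    seen: dict[tuple[str, str], float] = {}
    order: list[str] = []
    for _, (a, b, s) in body.iterrows():
        a, b = str(a), str(b)
        if a == b:
            raise ValidationError(f"{path}: self-loop row on gene {a!r}")
        try:
            w = float(s)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric score {s!r} for pair ({a}, {b})") from None
        key = (min(a, b), max(a, b))
        if key in seen and seen[key] != w:
            raise ValidationError(
                f"{path}: conflicting duplicate pair {key}: {seen[key]} vs {w}"
            )
        seen[key] = w
        for g in (a, b):
            if g not in order:
                order.append(g)
    if gene_ids is not None:
        unknown = [g for g in order if g not in set(gene_ids)]
        if unknown:
            raise ValidationError(f"{path}: genes not in the requested set: {unknown}")
        order = list(gene_ids)
    index = {g: i for i, g in enumerate(order)}
    scores = np.zeros((len(order), len(order)))
    for (a, b), w in seen.items():
        scores[index[a], index[b]] = scores[index[b], index[a]] = w
    return WeightedNetwork(tuple(order), scores)


def _reindex(net: WeightedNetwork, gene_ids) -> WeightedNetwork:
    gene_ids = list(gene_ids)
    unknown = [g for g in net.gene_ids if g not in set(gene_ids)]
    if unknown:
        raise ValidationError(f"genes not in the requested set: {unknown}")
    index = {g: i for i, g in enumerate(net.gene_ids)}
    p = len(gene_ids)
    scores = np.zeros((p, p))
    for a, b in itertools.combinations(range(p), 2):
        ga, gb = gene_ids[a], gene_ids[b]
        if ga in index and gb in index:
            scores[a, b] = scores[b, a] = net.scores[index[ga], index[gb]]
    return WeightedNetwork(tuple(gene_ids), scores)


def write_network(
    net: WeightedNetwork,
    path,
    format: str = "edgelist",
    threshold: float = 0.0,
    delimiter: str = "\t",
) -> None:
    """Write a network as an edge list (pairs with |score| > threshold,
    lexicographically sorted) or as the full labelled square matrix."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if format == "matrix":
        df = pd.DataFrame(net.scores, index=list(net.gene_ids), columns=list(net.gene_ids))
        df.to_csv(path, sep=delimiter, index_label="", float_format="%.12g")
        return
    if format != "edgelist":
        raise ValidationError(f"unknown network format {format!r}")
    rows = []
    for (a, b) in itertools.combinations(sorted(net.gene_ids), 2):
        ia = net.gene_ids.index(a)
        ib = net.gene_ids.index(b)
        w = net.scores[ia, ib]
        if abs(w) > threshold:
            rows.append((a, b, w))
    buf = io.StringIO()
    buf.write(delimiter.join(("gene_a", "gene_b", "score")) + "\n")
    for a, b, w in rows:
        buf.write(delimiter.join((a, b, format_score(w))) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def format_score(w: float) -> str:
    return f"{w:.12g}"


# ---------------------------------------------------------------------------
# gold-standard I/O


def read_truth(path, gene_ids=None, delimiter: str = "\t") -> TrueNetwork:
    """Read a gold standard from a 2- or 3-column edge list (scores, if
    present, are ignored)."""
    raw = _read_table(path, delimiter)
    if raw.shape[1] not in (2, 3):
        raise ParseError(f"{path}: expected a 2- or 3-column edge list, got {raw.shape[1]} columns")
    body = raw.iloc[1:]
    edges = set()
    order: list[str] = []
    for _, row in body.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        edges.add((min(a, b), max(a, b)))
        for g in (a, b):
            if g not in order:
                order.append(g)
    ids = tuple(gene_ids) if gene_ids is not None else tuple(order)
    return TrueNetwork(ids, frozenset(edges))


def write_truth(truth: TrueNetwork, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(("gene_a", "gene_b")) + "\n")
        for a, b in sorted(truth.edges):
            fh.write(delimiter.join((a, b)) + "\n")
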