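"""Readers/writers for expression matrices, signed edge lists, gold standards
and ranked edge predictions, plus the shared domain types.

All on-disk formats are plain TSV:

* expression matrix — header row of sample ids (optionally preceded by a
  corner label), one row per gene, first column the gene id, numeric body;
* signed edge list — 2 or 3 columns ``regulator  target  [sign]`` where the
  sign column accepts ``1/+1/+`` and ``-1/−1/-`` and defaults to ``+1``;
* ranked edges — ``gene_i  gene_j  weight`` over all unordered pairs, sorted
  by descending weight, ties broken by lexicographic pair id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SignedNetwork",
    "UndirectedTruth",
    "WeightMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signed_edge_list",
    "write_signed_edge_list",
    "to_undirected_truth",
    "write_ranked_edges",
    "read_ranked_edges",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    ``values[i, k]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[k]``. Row order is canonical for all downstream matrices.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None


@dataclass
class SignedNetwork:
    """Directed, signed regulator->target graph; simulation ground truth."""

    gene_ids: list[str]
    edges: set[tuple[str, str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        genes = set(self.gene_ids)
        pairs = set()
        for reg, tgt, sign in self.edges:
            if reg not in genes or tgt not in genes:
                raise ValueError(f"edge endpoint not in gene_ids: {(reg, tgt)}")
            if sign not in (+1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            if (reg, tgt) in pairs:
                raise ValueError(f"duplicate edge: {(reg, tgt)}")
            pairs.add((reg, tgt))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def self_edges(self) -> set[tuple[str, str, int]]:
        """Self-loops are tolerated on read but flagged here."""
        return {e for e in self.edges if e[0] == e[1]}


@dataclass
class UndirectedTruth:
    """Gold standard: set of unordered gene pairs (no self-pairs)."""

    gene_ids: list[str]
    pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        genes = set(self.gene_ids)
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"not an unordered pair of distinct genes: {set(p)}")
            if not p <= genes:
                raise ValueError(f"pair endpoint not in gene_ids: {set(p)}")

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs


@dataclass
class WeightMatrix:
    """Symmetric gene x gene predicted interaction weights.

    Orientation contract: larger weight means higher edge confidence. The
    diagonal is defined but ignored by evaluation.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape}, expected ({n}, {n})")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first col = gene ids).

    Rejects non-numeric cells (naming the offending gene/sample), duplicate
    ids, and ragged rows (reporting the line number).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header and at least one gene row")
    header = lines[0].split("\t")
    body = [ln.split("\t") for ln in lines[1:]]
    width = len(body[0])
    for lineno, row in enumerate(body, start=2):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row at line {lineno} "
                             f"({len(row)} fields, expected {width})")
    if len(header) == width:
        sample_ids = header[1:]  # corner label present
    elif len(header) == width - 1:
        sample_ids = header
    else:
        raise ValueError(f"{path}: header has {len(header)} fields but data rows "
                         f"have {width}")
    gene_ids = [row[0] for row in body]
    values = np.empty((len(body), len(sample_ids)), dtype=float)
    for i, row in enumerate(body):
        for k, cell in enumerate(row[1:]):
            try:
                values[i, k] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} for gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[k]!r}"
                ) from None
        if not np.all(np.isfinite(values[i])):
            k = int(np.flatnonzero(~np.isfinite(values[i]))[0])
            raise ValueError(f"{path}: non-finite cell for gene {gene_ids[i]!r}, "
                             f"sample {sample_ids[k]!r}")
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(em.sample_ids) + "\n")
        for gid, row in zip(em.gene_ids, em.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# edge list I/O

_SIGN_TOKENS = {"1": +1, "+1": +1, "+": +1, "-1": -1, "−1": -1, "-": -1,
                "−": -1}


def read_signed_edge_list(path) -> SignedNetwork:
    """Read a 2- or 3-column TSV edge list; missing sign column means +1.

    Gene ids are collected in first-appearance order (regulator before
    target, line by line).
    """
    gene_ids: list[str] = []
    seen_genes: set[str] = set()
    edges: set[tuple[str, str, int]] = set()
    seen_pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if ln.strip() == "":
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns, "
                                 f"got {len(fields)}")
            reg, tgt = fields[0], fields[1]
            if len(fields) == 3:
                token = fields[2].strip()
                if token not in _SIGN_TOKENS:
                    raise ValueError(f"{path}: line {lineno}: unknown sign token "
                                     f"{token!r}")
                sign = _SIGN_TOKENS[token]
            else:
                sign = +1
            if (reg, tgt) in seen_pairs:
                raise ValueError(f"{path}: line {lineno}: duplicate edge "
                                 f"({reg!r}, {tgt!r})")
            seen_pairs.add((reg, tgt))
            for g in (reg, tgt):
                if g not in seen_genes:
                    seen_genes.add(g)
                    gene_ids.append(g)
            edges.add((reg, tgt, sign))
    return SignedNetwork(gene_ids, edges)


def write_signed_edge_list(net: SignedNetwork, path) -> None:
    order = {g: i for i, g in enumerate(net.gene_ids)}
    with open(path, "w") as fh:
        for reg, tgt, sign in sorted(net.edges, key=lambda e: (order[e[0]], order[e[1]])):
            fh.write(f"{reg}\t{tgt}\t{sign:+d}\n")


def to_undirected_truth(net: SignedNetwork) -> UndirectedTruth:
    """Collapse a directed signed network to unordered pairs.

    Self-edges are dropped and reciprocal edges collapse to one pair, so the
    result is invariant under reversing any edge's direction.
    """
    pairs = {frozenset((reg, tgt)) for reg, tgt, _ in net.edges if reg != tgt}
    return UndirectedTruth(list(net.gene_ids), pairs)


# ---------------------------------------------------------------------------
# ranked predictions


def ranked_pairs(w: WeightMatrix) -> list[tuple[str, str, float]]:
    """All unordered pairs sorted by weight desc, ties by lexicographic ids."""
    rows = []
    ids = w.gene_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            rows.append((a, b, float(w.weights[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows


def write_ranked_edges(w: WeightMatrix, path) -> None:
    with open(path, "w") as fh:
        for a, b, weight in ranked_pairs(w):
            fh.write(f"{a}\t{b}\t{weight!r}\n")


def read_ranked_edges(path, gene_ids: list[str] | None = None) -> WeightMatrix:
    """Read a ranked prediction file back into a WeightMatrix.

    If ``gene_ids`` is given, it fixes gene order and unlisted pairs get a
    weight strictly below the listed minimum; otherwise ids are collected in
    first-appearance order and the file must cover every pair.
    """
    triples: list[tuple[str, str, float]] = []
    seen: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if ln.strip() == "":
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            a, b, wt = fields[0], fields[1], float(fields[2])
            triples.append((a, b, wt))
            for g in (a, b):
                if g not in seen_set:
                    seen_set.add(g)
                    seen.append(g)
    ids = list(gene_ids) if gene_ids is not None else seen
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    floor = (min(t[2] for t in triples) - 1.0) if triples else 0.0
    weights = np.full((n, n), floor)
    np.fill_diagonal(weights, 0.0)
    for a, b, wt in triples:
        if a not in index or b not in index:
            if gene_ids is not None:
                raise ValueError(f"{path}: gene {a!r}/{b!r} not in supplied gene_ids")
        i, j = index[a], index[b]
        weights[i, j] = weights[j, i] = wt
    if gene_ids is None and len(triples) != n * (n - 1) // 2:
        raise ValueError(f"{path}: expected {n * (n - 1) // 2} pair lines for "
                         f"{n} genes, got {len(triples)}")
    return WeightMatrix(ids, weights)
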