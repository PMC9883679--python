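"""Undirected gene interaction networks: loading, validation, normalization.

The interactome is an undirected graph over gene identifiers with a symmetric,
zero-diagonal adjacency matrix A. By default edges are binarized (presence /
absence above a confidence threshold); an optional weighted mode keeps raw
edge weights, in which case degrees become weighted sums.

The diffusion step consumes the symmetrically normalized adjacency

    w_ij = a_ij / sqrt(d_i * d_j)

whose spectral radius is at most 1, which guarantees convergence of the
random-walk-with-restart iteration for any restart parameter in (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "load_edge_list",
    "write_edge_list",
    "normalize",
    "align",
    "load_gmt",
    "write_gmt",
]


@dataclass
class Interactome:
    """An undirected network over an ordered list of gene identifiers.

    Attributes
    ----------
    genes:
        Ordered unique gene identifiers.
    adjacency:
        Symmetric N x N sparse matrix with zero diagonal. Binary {0, 1}
        unless the network was loaded with ``binarize=False``.
    """

    genes: list[str]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        if self.adjacency.shape != (len(self.genes), len(self.genes)):
            raise ValueError("adjacency shape does not match gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        if self.adjacency.nnz and self.adjacency.data.min() < 0:
            raise ValueError("edge weights must be nonnegative")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def degrees(self) -> np.ndarray:
        """Number of neighbours of each gene (count of nonzero entries)."""
        return np.diff(self.adjacency.indptr)

    @property
    def strengths(self) -> np.ndarray:
        """Weighted degrees (row sums); equals ``degrees`` for binary nets."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def neighbors(self, gene: str) -> list[str]:
        i = self._index[gene]
        row = self.adjacency.indices[self.adjacency.indptr[i]: self.adjacency.indptr[i + 1]]
        return [self.genes[j] for j in row]

    def subset(self, genes: Iterable[str]) -> "Interactome":
        """Induced subgraph on ``genes`` (order preserved)."""
        genes = list(genes)
        idx = np.array([self._index[g] for g in genes], dtype=int)
        return Interactome(genes, self.adjacency[np.ix_(idx, idx)])


def load_edge_list(
    path: str | Path,
    weight_threshold: float = 0.0,
    binarize: bool = True,
) -> Interactome:
    """Load an undirected network from a 2- or 3-column TSV edge list.

    Lines starting with ``#`` are ignored; a single header line is detected
    when its third field is non-numeric (or, for 2-column files, when the
    first line repeats no gene seen later -- headers are simply skipped when
    the weight column fails to parse). Duplicate and reversed-duplicate edges
    are collapsed keeping the maximum weight; self-loops are dropped. With
    ``binarize`` (default) every kept edge with weight >= ``weight_threshold``
    becomes 1; otherwise raw weights are kept.
    """
    path = Path(path)
    if weight_threshold < 0:
        raise ValueError("weight_threshold must be nonnegative")
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    if first_data_line:
                        first_data_line = False
                        continue  # header line
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}")
            else:
                w = 1.0
            first_data_line = False
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            rows.append((parts[0], parts[1], w))
    if not rows:
        raise ValueError(f"{path}: no edges found")
    return from_edges(rows, weight_threshold=weight_threshold, binarize=binarize)


def from_edges(
    edges: Iterable[tuple[str, str] | tuple[str, str, float]],
    weight_threshold: float = 0.0,
    binarize: bool = True,
) -> Interactome:
    """Build an :class:`Interactome` from in-memory edge tuples.

    Same dedup / self-loop / threshold semantics as :func:`load_edge_list`.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[str] = []
    seen: set[str] = set()
    for e in edges:
        a, b = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else 1.0
        if w < 0:
            raise ValueError(f"negative weight on edge ({a}, {b})")
        for g in (a, b):
            if g not in seen:
                seen.add(g)
                order.append(g)
        if a == b:
            continue  # self-loop
        key = (a, b) if a <= b else (b, a)
        if key not in best or w > best[key]:
            best[key] = w
    kept = {k: w for k, w in best.items() if w >= weight_threshold}
    n_dropped = len(best) - len(kept)
    if n_dropped:
        logger.info("dropped %d edges below weight threshold", n_dropped)
    index = {g: i for i, g in enumerate(order)}
    n = len(order)
    if kept:
        ii = np.fromiter((index[a] for a, _ in kept), dtype=int, count=len(kept))
        jj = np.fromiter((index[b] for _, b in kept), dtype=int, count=len(kept))
        ww = np.ones(len(kept)) if binarize else np.fromiter(kept.values(), dtype=float)
        adj = sp.coo_matrix((np.r_[ww, ww], (np.r_[ii, jj], np.r_[jj, ii])), shape=(n, n))
    else:
        adj = sp.coo_matrix((n, n))
    return Interactome(order, adj.tocsr())


def from_networkx(graph) -> Interactome:
    """Build a binary :class:`Interactome` from an undirected networkx graph.

    Isolated nodes are kept; self-loops are dropped; weights are ignored.
    """
    import networkx as nx

    nodelist = list(graph.nodes())
    genes = [str(g) for g in nodelist]
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, weight=None, format="csr")
    adj = sp.csr_matrix(adj, dtype=float)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return Interactome(genes, adj)


def write_edge_list(net: Interactome, path: str | Path) -> None:
    """Write the upper triangle of the adjacency as a 3-column TSV."""
    coo = sp.triu(net.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{net.genes[i]}\t{net.genes[j]}\t{w:.17g}\n")


def normalize(net: Interactome, weighted: bool = False) -> sp.csr_matrix:
    """Symmetric normalization W with w_ij = a_ij / sqrt(d_i * d_j).

    Rows and columns of degree-0 genes are all zero. In weighted mode the
    degrees are the weighted row sums. Every eigenvalue of W lies in [-1, 1].
    """
    d = net.strengths if weighted else net.degrees.astype(float)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(inv_sqrt)
    return (D @ net.adjacency @ D).tocsr()


def align(
    net: Interactome,
    scores,
    policy: Literal["intersect", "union-fill-zero"] = "intersect",
):
    """Reconcile the gene universes of a network and a score matrix.

    ``intersect`` keeps genes present on both sides (dropped genes logged);
    ``union-fill-zero`` keeps every network gene, filling missing score rows
    with zeros. Both outputs share an identical gene order.
    """
    from .diffusion import ScoreMatrix  # local import to avoid a cycle

    net_set = set(net.genes)
    score_set = set(scores.genes)
    if policy == "intersect":
        keep = [g for g in net.genes if g in score_set]
        if not keep:
            raise ValueError("empty gene intersection between network and scores")
        dropped_net = len(net.genes) - len(keep)
        dropped_scores = len(scores.genes) - len(keep)
        if dropped_net or dropped_scores:
            logger.info(
                "align(intersect): dropped %d network-only and %d score-only genes",
                dropped_net, dropped_scores,
            )
        new_net = net.subset(keep)
        rows = [scores.index_of(g) for g in keep]
        return new_net, ScoreMatrix(keep, list(scores.layers), scores.X[rows, :])
    elif policy == "union-fill-zero":
        keep = list(net.genes)
        X = np.zeros((len(keep), scores.n_layers))
        for r, g in enumerate(keep):
            if g in score_set:
                X[r] = scores.X[scores.index_of(g)]
        n_filled = len(keep) - len(net_set & score_set)
        if n_filled:
            logger.info("align(union-fill-zero): %d genes filled with zero scores", n_filled)
        return net.subset(keep), ScoreMatrix(keep, list(scores.layers), X)
    raise ValueError(f"unknown align policy {policy!r}")


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")
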