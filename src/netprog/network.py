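"""Protein-protein interaction network loading and normalization.

The propagation stage works on the column-normalized adjacency matrix W of
an undirected, unweighted interaction network: entry ``W[i, j]`` is
``A[i, j] / degree(j)``, so each column of W is the transition distribution
out of gene *j* and propagation conserves probability mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["InteractionNetwork", "read_edge_list", "column_normalize", "from_edges"]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class InteractionNetwork:
    """An undirected, unweighted gene interaction network.

    Attributes
    ----------
    nodes:
        Gene identifiers in deterministic (lexicographic) order.
    edges:
        Set of unordered gene pairs stored as sorted tuples; no self-loops.
    W:
        Column-normalized sparse transition matrix (CSC), populated by
        :func:`column_normalize`. ``W[i, j] = A[i, j] / degree(j)``.
    report:
        Load report: counts of nodes, edges and removed lines.
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    W: sp.csc_matrix | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=int)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in node order."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        ii, jj = [], []
        for a, b in self.edges:
            ia, ib = self._index[a], self._index[b]
            ii.extend((ia, ib))
            jj.extend((ib, ia))
        data = np.ones(len(ii))
        return sp.csr_matrix((data, (ii, jj)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[self._index[a]] += 1
            deg[self._index[b]] += 1
        return deg

    def report_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in sorted(self.report.items()))


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def from_edges(pairs: Iterable[tuple[str, str]], drop_self_loops: bool = True,
               drop_duplicates: bool = True) -> InteractionNetwork:
    """Build a simple undirected network from an iterable of gene pairs."""
    edges: set[tuple[str, str]] = set()
    n_self = n_dup = 0
    nodes: set[str] = set()
    for a, b in pairs:
        nodes.update((a, b))
        if a == b:
            if drop_self_loops:
                n_self += 1
                continue
            raise EdgeListError(f"self-loop on {a!r} and drop_self_loops is off")
        e = _canonical(a, b)
        if e in edges:
            n_dup += 1
            if not drop_duplicates:
                raise EdgeListError(f"duplicate edge {e}")
            continue
        edges.add(e)
    net = InteractionNetwork(nodes=sorted(nodes), edges=edges)
    net.report = {
        "nodes": len(net.nodes),
        "edges": len(edges),
        "self_loops_removed": n_self,
        "duplicates_removed": n_dup,
    }
    return net


def read_edge_list(path: str | Path, drop_self_loops: bool = True,
                   drop_duplicates: bool = True) -> InteractionNetwork:
    """Read a two-or-more-column delimited edge list into a network.

    The first two whitespace/tab-delimited columns are gene identifiers;
    extra columns (e.g. a SIF interaction-type column) are ignored.
    Raises :class:`EdgeListError` naming the line number on malformed
    lines, and on an empty file.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(f"{path}:{lineno}: malformed edge line {line!r}")
            pairs.append((parts[0].strip(), parts[1].strip()))
    if not pairs:
        raise EdgeListError(f"{path}: empty edge list")
    return from_edges(pairs, drop_self_loops=drop_self_loops,
                      drop_duplicates=drop_duplicates)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def column_normalize(network: InteractionNetwork) -> InteractionNetwork:
    """Populate W, the column-normalized adjacency matrix.

    Isolated (degree-0) nodes would leave an all-zero column, breaking
    column stochasticity, so they are removed first with a logged warning;
    seeds that fall on removed nodes surface later as "unmapped" in the
    start-probability report.
    """
    deg = network.degrees()
    isolated = [g for g, d in zip(network.nodes, deg) if d == 0]
    if isolated:
        logger.warning("removing %d isolated node(s) before normalization", len(isolated))
        network = InteractionNetwork(
            nodes=[g for g in network.nodes if g not in set(isolated)],
            edges=set(network.edges),
            report=dict(network.report),
        )
        deg = network.degrees()
    network.report["isolated_removed"] = len(isolated)
    A = network.adjacency().tocsc()
    inv_deg = 1.0 / deg.astype(float)
    # scale column j by 1/degree(j)
    W = A @ sp.diags(inv_deg)
    network.W = sp.csc_matrix(W)
    return network
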