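"""Seed evidence: gene-set membership and mutation counts to start probabilities.

Two evidence channels feed the walk: the number of prognostic expression
signatures a gene belongs to (s_i) and the number of distinct somatic
variants catalogued for it (m_i). The integrated start distribution gives
equal total weight to the two channels and, within a channel, weight
proportional to the evidence count:

    p0_i = 1/2 * s_i / sum_j s_j + 1/2 * m_i / sum_j m_j

with the sums running over genes that map onto the network. Single-channel
modes ("NE": expression signatures only, "NM": mutations only) drop the
other term and renormalize.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from netprog.network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCollection",
    "MutationCatalog",
    "StartProbabilityVector",
    "count_signature_membership",
    "compute_start_probabilities",
    "read_gmt",
    "read_mutation_catalog",
]

MODES = ("NEM", "NE", "NM")


@dataclass
class SignatureCollection:
    """Named gene sets plus per-gene membership counts s_i."""

    signatures: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.membership_count = count_signature_membership(self.signatures)

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    @property
    def all_genes(self) -> set[str]:
        return set().union(*self.signatures.values()) if self.signatures else set()

    def drop(self, name: str) -> "SignatureCollection":
        """Collection with one signature held out (leave-one-out runs)."""
        return SignatureCollection(
            {k: set(v) for k, v in self.signatures.items() if k != name}
        )


@dataclass
class MutationCatalog:
    """Per-gene counts of distinct catalogued somatic variants m_i."""

    variant_count: dict[str, int]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.variant_count.items() if c < 1}
        if bad:
            raise ValueError(f"variant counts must be >= 1; offending entries: {bad}")


@dataclass
class StartProbabilityVector:
    """Start distribution p0 over network nodes, with mapping provenance."""

    p0: np.ndarray
    nodes: list[str]
    n: int  # total number of genes in the interaction network
    channel_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p0.shape != (len(self.nodes),):
            raise ValueError("p0 length does not match node list")
        if np.any(self.p0 < 0):
            raise ValueError("start probabilities must be non-negative")
        if abs(self.p0.sum() - 1.0) > 1e-12:
            raise ValueError(f"start probabilities sum to {self.p0.sum()!r}, not 1")


def count_signature_membership(signatures: dict[str, set[str]]) -> dict[str, int]:
    """Number of gene sets each gene appears in (s_i)."""
    counts: dict[str, int] = {}
    for genes in signatures.values():
        if not genes:
            continue
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def _channel_weights(network: InteractionNetwork, counts: dict[str, int]) -> tuple[np.ndarray, list[str]]:
    """Normalized within-channel weights over network nodes; unmapped genes listed."""
    w = np.zeros(network.n_nodes)
    unmapped = []
    for g, c in counts.items():
        if g in network:
            w[network.index_of([g])[0]] = float(c)
        else:
            unmapped.append(g)
    total = w.sum()
    if total > 0:
        w = w / total
    return w, sorted(unmapped)


def compute_start_probabilities(
    network: InteractionNetwork,
    sigs: SignatureCollection | None,
    muts: MutationCatalog | None,
    mode: str = "NEM",
) -> StartProbabilityVector:
    """Map evidence onto network nodes and build the start distribution.

    Evidence genes absent from the network are dropped before channel
    normalization (the walk can only start on network nodes); they are
    listed in ``channel_report``. In NEM mode an empty channel hands its
    half of the weight to the other channel with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    s_counts = sigs.membership_count if sigs is not None else {}
    m_counts = dict(muts.variant_count) if muts is not None else {}

    ws, s_unmapped = _channel_weights(network, s_counts)
    wm, m_unmapped = _channel_weights(network, m_counts)
    s_ok, m_ok = ws.sum() > 0, wm.sum() > 0

    report = {
        "mode": mode,
        "n_signature_genes": len(s_counts),
        "n_signature_genes_unmapped": len(s_unmapped),
        "signature_genes_unmapped": s_unmapped,
        "n_mutation_genes": len(m_counts),
        "n_mutation_genes_unmapped": len(m_unmapped),
        "mutation_genes_unmapped": m_unmapped,
    }

    if mode == "NE":
        if not s_ok:
            raise ValueError("no signature gene maps onto the network")
        p0 = ws
    elif mode == "NM":
        if not m_ok:
            raise ValueError("no mutated gene maps onto the network")
        p0 = wm
    else:  # NEM
        if not s_ok and not m_ok:
            raise ValueError("no evidence gene maps onto the network")
        if not s_ok:
            warnings.warn("signature channel empty; full weight on mutation channel")
            p0 = wm
        elif not m_ok:
            warnings.warn("mutation channel empty; full weight on signature channel")
            p0 = ws
        else:
            p0 = 0.5 * ws + 0.5 * wm
    p0 = p0 / p0.sum()
    return StartProbabilityVector(
        p0=p0, nodes=list(network.nodes), n=network.n_nodes, channel_report=report
    )


def read_gmt(path: str | Path) -> SignatureCollection:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    signatures: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            signatures[parts[0]] = {g for g in parts[2:] if g}
    if not signatures:
        raise ValueError(f"{path}: empty GMT file")
    return SignatureCollection(signatures)


def write_gmt(sigs: SignatureCollection, path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name, genes in sigs.signatures.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_signature_dir(path: str | Path) -> SignatureCollection:
    """Read a directory of one-gene-per-line text files, one set per file."""
    path = Path(path)
    signatures = {}
    for f in sorted(path.glob("*.txt")):
        genes = {ln.strip() for ln in f.read_text().splitlines() if ln.strip()}
        if genes:
            signatures[f.stem] = genes
    if not signatures:
        raise ValueError(f"{path}: no non-empty signature files found")
    return SignatureCollection(signatures)


def read_mutation_catalog(path: str | Path) -> MutationCatalog:
    """Read a two-column TSV (gene, variant_count)."""
    counts: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("gene", "symbol"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>count")
            counts[parts[0]] = int(parts[1])
    if not counts:
        raise ValueError(f"{path}: empty mutation catalog")
    return MutationCatalog(counts)


def write_mutation_catalog(muts: MutationCatalog, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tvariant_count\n")
        for g in sorted(muts.variant_count):
            fh.write(f"{g}\t{muts.variant_count[g]}\n")
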