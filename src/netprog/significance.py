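"""Permutation significance of walk scores and signature extraction.

The null model shuffles the whole start-probability vector across network
nodes (preserving its multiset of values, hence the total seed mass and its
skew) and re-runs the walk; by default 1000 permutations. Each gene gets

* a local p-value — its real score ranked against its own null scores,
  guarding against genes that score high under any seeding because of
  network topology (hubs), and
* a global p-value — its real score ranked against the pooled null scores
  of all genes, measuring overall proximity to the actual seeds.

Both use the add-one empirical estimator (p >= 1/(N+1), never zero) with
ties counted conservatively (>=). Genes passing both thresholds form the
derived signature, split by provenance into seed-overlapping and
network-added genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from netprog.network import InteractionNetwork
from netprog.seeds import (
    MutationCatalog,
    SignatureCollection,
    StartProbabilityVector,
    compute_start_probabilities,
)
from netprog.walk import CachedSolver, DEFAULT_RESTART, WalkResult, rwr_solve_exact

__all__ = [
    "PermutationNull",
    "SignificanceResult",
    "permute_start_probabilities",
    "empirical_p_values",
    "derive_signature",
    "leave_one_signature_out",
    "dice_coefficient",
    "run_prioritization",
]

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class PermutationNull:
    """Null walk scores from randomly permuted start probabilities."""

    random_scores: np.ndarray  # (n_perm, n_nodes)
    nodes: list[str]
    n_perm: int
    seed: int


@dataclass
class SignificanceResult:
    """Per-gene walk score with local/global empirical p-values."""

    nodes: list[str]
    scores: np.ndarray
    local_p: np.ndarray
    global_p: np.ndarray
    seed_genes: set[str] = field(default_factory=set)

    def significant(self, alpha: float = DEFAULT_ALPHA) -> list[str]:
        mask = (self.local_p < alpha) & (self.global_p < alpha)
        return [g for g, m in zip(self.nodes, mask) if m]

    def to_tsv(self, path: str | Path, alpha: float = DEFAULT_ALPHA) -> None:
        sig = set(self.significant(alpha))
        with Path(path).open("w") as fh:
            fh.write("gene\tscore\tlocal_p\tglobal_p\tsignificant\tprovenance\n")
            for i, g in enumerate(self.nodes):
                prov = "seed" if g in self.seed_genes else "network"
                fh.write(
                    f"{g}\t{self.scores[i]:.10g}\t{self.local_p[i]:.6g}\t"
                    f"{self.global_p[i]:.6g}\t{int(g in sig)}\t{prov}\n"
                )


def permute_start_probabilities(
    network: InteractionNetwork,
    p0: StartProbabilityVector,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    r: float = DEFAULT_RESTART,
) -> PermutationNull:
    """Walk ``n_perm`` random node-permutations of p0 to steady state.

    Each permutation draws from its own RNG stream spawned from ``seed``,
    so results are independent of batching or worker count. Steady states
    are obtained from one shared LU factorization of the walk system;
    this matches the iterative walk to well below its convergence
    tolerance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    solver = CachedSolver(network, r=r)
    n = network.n_nodes
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    perms = np.empty((n, n_perm))
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        perms[:, k] = p0.p0[rng.permutation(n)]
    scores = solver.solve(perms)  # batched right-hand sides
    return PermutationNull(
        random_scores=scores.T.copy(), nodes=list(network.nodes),
        n_perm=n_perm, seed=seed,
    )


def empirical_p_values(
    real: WalkResult,
    null: PermutationNull,
    seed_genes: set[str] | None = None,
) -> SignificanceResult:
    """Add-one local and global empirical p-values of real walk scores."""
    if real.nodes != null.nodes:
        raise ValueError("walk result and permutation null disagree on node order")
    n_perm, n_nodes = null.random_scores.shape
    # local: rank against the same gene's null scores
    exceed_local = (null.random_scores >= real.scores[None, :]).sum(axis=0)
    local_p = (1.0 + exceed_local) / (n_perm + 1.0)
    # global: rank against the pooled null scores of all genes
    pooled = np.sort(null.random_scores.ravel())
    exceed_global = pooled.size - np.searchsorted(pooled, real.scores, side="left")
    global_p = (1.0 + exceed_global) / (pooled.size + 1.0)
    return SignificanceResult(
        nodes=list(real.nodes),
        scores=real.scores.copy(),
        local_p=local_p,
        global_p=global_p,
        seed_genes=set(seed_genes or ()),
    )


def derive_signature(
    sig_result: SignificanceResult,
    alpha: float = DEFAULT_ALPHA,
    seed_genes: set[str] | None = None,
) -> dict:
    """Significant gene set at level alpha, split by provenance.

    Returns ``{"signature", "from_seeds", "network_added"}`` where the
    last two partition the signature by overlap with the seed genes.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    seeds = set(seed_genes) if seed_genes is not None else sig_result.seed_genes
    signature = set(sig_result.significant(alpha))
    return {
        "signature": signature,
        "from_seeds": signature & seeds,
        "network_added": signature - seeds,
    }


def dice_coefficient(a: set[str], b: set[str]) -> float:
    """Dice set overlap 2|A∩B| / (|A|+|B|)."""
    if not a and not b:
        raise ValueError("Dice coefficient undefined for two empty sets")
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def run_prioritization(
    network: InteractionNetwork,
    sigs: SignatureCollection | None,
    muts: MutationCatalog | None,
    mode: str = "NEM",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    r: float = DEFAULT_RESTART,
) -> tuple[SignificanceResult, dict]:
    """Seeds -> walk -> permutation null -> signature, in one call."""
    p0 = compute_start_probabilities(network, sigs, muts, mode=mode)
    real = rwr_solve_exact(network, p0, r=r)
    null = permute_start_probabilities(network, p0, n_perm=n_perm, seed=seed, r=r)
    seed_genes = {g for g, p in zip(network.nodes, p0.p0) if p > 0}
    result = empirical_p_values(real, null, seed_genes=seed_genes)
    return result, derive_signature(result, alpha=alpha)


def leave_one_signature_out(
    network: InteractionNetwork,
    sigs: SignatureCollection,
    muts: MutationCatalog | None,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    mode: str = "NEM",
) -> dict:
    """Hold out each expression signature in turn; Dice vs the full run.

    Returns the full signature, the per-holdout signatures, and min/mean/
    max Dice overlap with the full set — the robustness summary for the
    seed-list sensitivity analysis.
    """
    if len(sigs.signatures) < 2:
        raise ValueError("need at least two signatures to hold one out")
    _, full = run_prioritization(network, sigs, muts, mode=mode, alpha=alpha,
                                 n_perm=n_perm, seed=seed)
    holdout_sets: dict[str, set[str]] = {}
    dice: dict[str, float] = {}
    for name in sigs.names:
        reduced = sigs.drop(name)
        _, res = run_prioritization(network, reduced, muts, mode=mode,
                                    alpha=alpha, n_perm=n_perm, seed=seed)
        holdout_sets[name] = res["signature"]
        dice[name] = dice_coefficient(res["signature"], full["signature"])
    values = np.array(list(dice.values()))
    return {
        "full_signature": full["signature"],
        "holdout_signatures": holdout_sets,
        "dice": dice,
        "dice_min": float(values.min()),
        "dice_mean": float(values.mean()),
        "dice_max": float(values.max()),
    }
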