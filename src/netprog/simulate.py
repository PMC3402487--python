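"""Synthetic inputs with the structure the pipeline assumes.

The generator plants a densely connected "driver" module inside a
scale-free interaction network, enriches both evidence channels (gene-set
membership, mutation counts) in and around that module, and emits two
independent patient cohorts in which module genes load on a latent
per-sample risk that drives exponential relapse hazards with uniform
censoring. A treatment flag interacts with risk: adjuvant chemotherapy
multiplies the hazard by ``ctx_benefit_hazard_ratio`` only for patients
whose latent risk is above the cohort median, so treatment benefit is
confined to the (truly) high-risk stratum.

Defaults mirror the observed study conditions where these exist: eight
signatures with per-signature unique sizes {8, 58, 26, 24, 19, 22, 34,
21}, a few-hundred-gene mutation catalog with heavy-tailed variant
counts, cohorts of ~120 stage II/III samples, and an event fraction
around 0.28. The network scale (2000 genes) is a deliberate desk-scale
reduction of a ~11.5k-protein interactome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from netprog.network import InteractionNetwork, column_normalize, from_edges, write_edge_list
from netprog.seeds import (
    MutationCatalog,
    SignatureCollection,
    write_gmt,
    write_mutation_catalog,
)

__all__ = [
    "SyntheticConfig",
    "generate_network",
    "generate_evidence",
    "generate_expression_survival",
    "generate_all",
    "write_inputs",
]

SIGNATURE_SIZES = (8, 58, 26, 24, 19, 22, 34, 21)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the benchmark conditions."""

    n_genes: int = 2000
    attachment: int = 3          # preferential-attachment edges per new node
    module_size: int = 80
    module_density: float = 0.10
    signature_sizes: tuple = SIGNATURE_SIZES
    signature_module_fraction: float = 0.5
    n_mutated_genes: int = 150
    mutation_module_fraction: float = 0.4
    zipf_exponent: float = 2.0
    n_samples: int = 120
    beta: float = 1.0            # log-hazard effect of latent risk
    baseline_hazard: float = 0.02  # events per month at z = 0
    event_fraction: float = 0.28
    ctx_benefit_hazard_ratio: float = 0.4  # applies in the high-latent-risk half only
    complementary_evidence: bool = False   # signatures->one module half, mutations->other
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.module_size < self.n_genes):
            raise ValueError("module_size must be in (0, n_genes)")
        for f in (self.signature_module_fraction, self.mutation_module_fraction,
                  self.module_density, self.event_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if any(s > self.n_genes for s in self.signature_sizes):
            raise ValueError("signature sizes cannot exceed n_genes")


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_network(config: SyntheticConfig) -> tuple[InteractionNetwork, list[str]]:
    """Scale-free backbone with a planted densely connected module.

    A Barabasi-Albert graph provides the heavy-tailed backbone; a random
    subset of ``module_size`` nodes then receives extra within-module
    edges until the module's internal edge density reaches
    ``module_density``. Fully deterministic in the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    g = nx.barabasi_albert_graph(config.n_genes, config.attachment,
                                 seed=int(rng.integers(2**31)))
    module_idx = sorted(rng.choice(config.n_genes, size=config.module_size, replace=False))
    m = config.module_size
    target_edges = int(np.ceil(config.module_density * m * (m - 1) / 2))
    internal = {tuple(sorted(e)) for e in g.edges() if e[0] in set(module_idx) and e[1] in set(module_idx)}
    candidates = [(a, b) for k, a in enumerate(module_idx) for b in module_idx[k + 1:]
                  if (a, b) not in internal]
    need = max(0, target_edges - len(internal))
    if need > 0:
        chosen = rng.choice(len(candidates), size=need, replace=False)
        g.add_edges_from(candidates[c] for c in chosen)

    width = len(str(config.n_genes - 1))
    name = {i: _gene_name(i, width) for i in g.nodes()}
    net = from_edges((name[a], name[b]) for a, b in g.edges())
    net = column_normalize(net)
    module = sorted(name[i] for i in module_idx)
    return net, module


def _module_neighborhood(net: InteractionNetwork, module: list[str]) -> list[str]:
    member = set(module)
    hood = set(module)
    for a, b in net.edges:
        if a in member:
            hood.add(b)
        if b in member:
            hood.add(a)
    return sorted(hood)


def _sample_enriched(rng: np.random.Generator, size: int, enriched_pool: list[str],
                     all_genes: list[str], fraction: float) -> set[str]:
    n_mod = min(int(round(fraction * size)), len(enriched_pool))
    genes = set(rng.choice(enriched_pool, size=n_mod, replace=False))
    rest = [g for g in all_genes if g not in genes]
    n_rest = size - len(genes)
    genes.update(rng.choice(rest, size=n_rest, replace=False))
    return genes


def generate_evidence(config: SyntheticConfig, net: InteractionNetwork,
                      module: list[str]) -> tuple[SignatureCollection, MutationCatalog]:
    """Signatures and mutation catalog enriched in/around the module.

    Each evidence set draws its enriched fraction from the module plus
    its 1-hop neighborhood (so the evidence differs from the module and
    propagation has genuine work to do) and the rest uniformly. With
    ``complementary_evidence`` the signatures see only one half of the
    module and the mutations only the other half — the benchmark on which
    integrating both channels should beat either alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    all_genes = list(net.nodes)
    if config.complementary_evidence:
        half = len(module) // 2
        sig_module, mut_module = module[:half], module[half:]
    else:
        sig_module = mut_module = module
    sig_pool = _module_neighborhood(net, sig_module)
    mut_pool = _module_neighborhood(net, mut_module)

    signatures = {}
    for k, size in enumerate(config.signature_sizes, start=1):
        signatures[f"signature_{k}"] = _sample_enriched(
            rng, size, sig_pool, all_genes, config.signature_module_fraction)
    sigs = SignatureCollection(signatures)

    enriched = _sample_enriched(rng, config.n_mutated_genes, mut_pool,
                                all_genes, config.mutation_module_fraction)
    pool_set = set(mut_pool)
    drivers = sorted(g for g in enriched if g in pool_set)
    passengers = sorted(g for g in enriched if g not in pool_set)
    counts = np.minimum(rng.zipf(config.zipf_exponent, size=len(enriched)), 100)
    # driver genes accumulate the most distinct variants: the largest
    # counts go to the module-pool genes, so the channel's *mass* (not
    # just its membership) is enriched in the module; passengers mostly
    # carry singletons, as the Zipf tail dictates
    counts = np.sort(counts)[::-1]
    gene_order = list(rng.permutation(drivers)) + list(rng.permutation(passengers))
    muts = MutationCatalog({g: int(c) for g, c in zip(gene_order, counts)})
    return sigs, muts


def _calibrate_censoring(rates: np.ndarray, target_event_fraction: float) -> float:
    """Upper bound of Uniform(0, cmax) censoring hitting the event target.

    For T ~ Exp(rate) and C ~ U(0, cmax), P(event) = 1 - (1 - e^{-r cmax})
    / (r cmax), averaged over the cohort's rates; solve for cmax.
    """

    def frac(cmax: float) -> float:
        x = rates * cmax
        return float(np.mean(1.0 - (1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e6
    if frac(hi) < target_event_fraction:
        return hi
    return brentq(lambda c: frac(c) - target_event_fraction, lo, hi, xtol=1e-9)


def _module_loadings(config: SyntheticConfig, n_module: int) -> np.ndarray:
    """Per-gene risk loadings: shared "biology", identical in both cohorts."""
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 5]))
    return rng.uniform(0.4, 1.0, size=n_module) * rng.choice([-1.0, 1.0], size=n_module)


def _generate_cohort(config: SyntheticConfig, module: list[str], all_genes: list[str],
                     rng: np.random.Generator, cohort_name: str,
                     loadings: np.ndarray) -> dict:
    n = config.n_samples
    z = rng.standard_normal(n)  # latent per-sample risk

    expr = rng.standard_normal((len(all_genes), n))
    mod_idx = [all_genes.index(g) for g in module]
    expr[mod_idx, :] += np.outer(loadings, z)

    ctx = rng.integers(0, 2, size=n)
    high_latent = z > np.median(z)
    hazard = config.baseline_hazard * np.exp(config.beta * z)
    hazard = hazard * np.where(high_latent & (ctx == 1), config.ctx_benefit_hazard_ratio, 1.0)

    t_event = rng.exponential(1.0 / hazard)
    cmax = _calibrate_censoring(hazard, config.event_fraction)
    t_cens = rng.uniform(0.0, cmax, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # strictly positive follow-up

    stage_p = 1.0 / (1.0 + np.exp(-0.8 * z))  # higher latent risk -> more stage III
    stage = np.where(rng.uniform(size=n) < stage_p, "III", "II")
    age = np.round(rng.normal(65.0, 10.0, size=n), 1)
    gender = rng.choice(["M", "F"], size=n)

    samples = [f"{cohort_name}_S{i:03d}" for i in range(n)]
    expression = pd.DataFrame(expr, index=all_genes, columns=samples)
    clinical = pd.DataFrame(
        {
            "time": np.round(time, 4),
            "event": event,
            "stage": stage,
            "age": age,
            "gender": gender,
            "ctx": ctx,
        },
        index=pd.Index(samples, name="sample"),
    )
    return {"expression": expression, "clinical": clinical, "latent_risk": pd.Series(z, index=samples)}


def generate_expression_survival(config: SyntheticConfig, module: list[str],
                                 all_genes: list[str] | None = None) -> tuple[dict, dict]:
    """Two independent cohorts from the same generative mechanism.

    Returns (cohort1, cohort2); each dict holds ``expression`` (gene x
    sample), ``clinical``, and the true ``latent_risk`` for oracle checks.
    """
    if all_genes is None:
        width = len(str(config.n_genes - 1))
        all_genes = [_gene_name(i, width) for i in range(config.n_genes)]
    rng1 = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    rng2 = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 4]))
    loadings = _module_loadings(config, len(module))
    return (
        _generate_cohort(config, module, all_genes, rng1, "C1", loadings),
        _generate_cohort(config, module, all_genes, rng2, "C2", loadings),
    )


def generate_all(config: SyntheticConfig) -> dict:
    """Network, module, evidence and both cohorts in one bundle."""
    net, module = generate_network(config)
    sigs, muts = generate_evidence(config, net, module)
    cohort1, cohort2 = generate_expression_survival(config, module, list(net.nodes))
    return {
        "network": net,
        "module": module,
        "signatures": sigs,
        "mutations": muts,
        "cohort1": cohort1,
        "cohort2": cohort2,
    }


def write_inputs(bundle: dict, outdir: str | Path, config: SyntheticConfig) -> None:
    """Write every input in the formats the pipeline reads, plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(bundle["network"], outdir / "network_edges.tsv")
    write_gmt(bundle["signatures"], outdir / "signatures.gmt")
    write_mutation_catalog(bundle["mutations"], outdir / "mutations.tsv")
    (outdir / "module_genes.txt").write_text("\n".join(bundle["module"]) + "\n")
    for name in ("cohort1", "cohort2"):
        bundle[name]["expression"].to_csv(outdir / f"{name}_expression.tsv", sep="\t")
        bundle[name]["clinical"].to_csv(outdir / f"{name}_clinical.tsv", sep="\t", na_rep="NA")
    manifest = {"config": asdict(config)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")
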