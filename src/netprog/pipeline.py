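"""End-to-end orchestration: seeds -> walk -> signature -> SSVM -> survival.

A run takes either a directory of input files (edge list, GMT, mutation
TSV, expression + clinical TSVs for two cohorts) or a synthetic-data
configuration, derives the network signature in the requested mode,
trains the kernel survival SVM on one cohort with grid-searched (c,
sigma), scores the other cohort, and reports risk stratification,
log-rank / Cox statistics and the treatment-benefit analysis. All
randomness flows from one root seed, split per stage, so a rerun with
the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from netprog import expression as xprep
from netprog.network import InteractionNetwork, column_normalize, read_edge_list
from netprog.seeds import (
    MutationCatalog,
    SignatureCollection,
    read_gmt,
    read_mutation_catalog,
)
from netprog.significance import run_prioritization, leave_one_signature_out
from netprog.simulate import SyntheticConfig, generate_all
from netprog.ssvm import (
    CVGrid,
    DEFAULT_GRID_VALUES,
    grid_search_cv,
    median_stratify,
    predict_risk_scores,
)
from netprog.survstats import (
    concordance_index,
    cox_fit,
    ctx_benefit_analysis,
    kaplan_meier,
    logrank_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_full_pipeline",
    "run_mode_comparison",
    "random_signature_baseline",
    "alpha_sweep",
]

MODES = ("NEM", "NE", "NM", "union", "signatures-only", "mutations-only")
NETWORK_MODES = ("NEM", "NE", "NM")
THREE_YEARS_MONTHS = 36.0


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source (files or synthetic)."""

    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    mode: str = "NEM"
    alpha: float = 0.05
    n_perm: int = 1000
    restart: float = 0.5
    c_values: tuple = DEFAULT_GRID_VALUES
    sigma_values: tuple = DEFAULT_GRID_VALUES
    cv_folds: int = 5
    cv_repeats: int = 5
    reverse: bool = False     # train on cohort2 / test on cohort1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir / synthetic must be given")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


_STAGE_OFFSETS = {"permutations": 11, "cv": 12, "baseline": 13}


def _stage_seed(root: int, stage: str) -> int:
    ss = np.random.SeedSequence([root, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % 2**31)


def load_inputs(config: RunConfig) -> dict:
    """Load (or generate) network, evidence and the two cohorts."""
    if config.synthetic is not None:
        return generate_all(config.synthetic)
    d = Path(config.input_dir)
    net = column_normalize(read_edge_list(d / "network_edges.tsv"))
    bundle = {
        "network": net,
        "signatures": read_gmt(d / "signatures.gmt"),
        "mutations": read_mutation_catalog(d / "mutations.tsv"),
    }
    for name in ("cohort1", "cohort2"):
        bundle[name] = {
            "expression": xprep.read_expression(d / f"{name}_expression.tsv"),
            "clinical": xprep.read_clinical(d / f"{name}_clinical.tsv"),
        }
    module_file = d / "module_genes.txt"
    if module_file.exists():
        bundle["module"] = module_file.read_text().split()
    return bundle


def select_signature(bundle: dict, config: RunConfig) -> tuple[set[str], dict]:
    """Gene set for model training, per the run mode.

    Network modes (NEM/NE/NM) run the full prioritization (walk +
    permutation null + dual-p thresholding); the remaining modes use the
    raw seed genes without any propagation.
    """
    sigs: SignatureCollection = bundle["signatures"]
    muts: MutationCatalog = bundle["mutations"]
    info: dict = {"mode": config.mode, "walk_executed": config.mode in NETWORK_MODES}
    if config.mode in NETWORK_MODES:
        use_sigs = sigs if config.mode in ("NEM", "NE") else None
        use_muts = muts if config.mode in ("NEM", "NM") else None
        result, derived = run_prioritization(
            bundle["network"], use_sigs, use_muts, mode=config.mode,
            alpha=config.alpha, n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "permutations"), r=config.restart,
        )
        info.update(
            signature_size=len(derived["signature"]),
            n_from_seeds=len(derived["from_seeds"]),
            n_network_added=len(derived["network_added"]),
        )
        return derived["signature"], info
    if config.mode == "union":
        genes = sigs.all_genes | set(muts.variant_count)
    elif config.mode == "signatures-only":
        genes = set(sigs.all_genes)
    else:  # mutations-only
        genes = set(muts.variant_count)
    info.update(signature_size=len(genes), n_from_seeds=len(genes), n_network_added=0)
    return genes, info


def evaluate_signature(bundle: dict, config: RunConfig, signature: set[str]) -> dict:
    """Train the SSVM on one cohort with the signature, test on the other."""
    train_key, test_key = ("cohort2", "cohort1") if config.reverse else ("cohort1", "cohort2")
    # cohorts standardized separately to preserve their independence
    X_train_all = xprep.zscore_genes(bundle[train_key]["expression"])
    X_test_all = xprep.zscore_genes(bundle[test_key]["expression"])
    X_train, missing_train = xprep.subset_to_signature(X_train_all, signature)
    X_test, _ = xprep.subset_to_signature(X_test_all, signature)
    clin_train = bundle[train_key]["clinical"]
    clin_test = bundle[test_key]["clinical"]

    grid = CVGrid(c_values=tuple(config.c_values), sigma_values=tuple(config.sigma_values),
                  folds=config.cv_folds, repeats=config.cv_repeats)
    grid, model = grid_search_cv(X_train, clin_train, grid=grid,
                                 seed=_stage_seed(config.seed, "cv"))
    scores = predict_risk_scores(model, X_test)
    cindex = concordance_index(scores.to_numpy(), clin_test["time"], clin_test["event"])
    groups = median_stratify(scores)
    labels = groups.to_numpy()
    lr = logrank_test(labels, clin_test["time"], clin_test["event"])
    high = pd.DataFrame({"high_risk": (labels == "high-risk").astype(float)},
                        index=clin_test.index)
    try:
        cox = cox_fit(high, clin_test["time"], clin_test["event"])
        hr, ci_lo, ci_hi = (float(cox.hazard_ratio[0]), float(cox.ci_lower[0]),
                            float(cox.ci_upper[0]))
        cox_p = float(cox.wald_p[0])
    except (RuntimeError, ValueError) as exc:
        logger.warning("Cox HR for risk group unavailable: %s", exc)
        hr = ci_lo = ci_hi = cox_p = float("nan")

    rfs3 = {}
    for label in ("low-risk", "high-risk"):
        mask = labels == label
        km = kaplan_meier(clin_test.loc[mask, "time"], clin_test.loc[mask, "event"])
        rfs3[label] = km.survival_at(THREE_YEARS_MONTHS)

    try:
        ctx = ctx_benefit_analysis(scores, clin_test)
        ctx_report = {
            k: {kk: vv for kk, vv in v.items() if kk != "km"} for k, v in ctx.items()
        }
    except ValueError as exc:
        ctx_report = {"error": str(exc)}

    return {
        "train_cohort": train_key,
        "test_cohort": test_key,
        "n_signature_genes_in_train": int(X_train.shape[0]),
        "n_signature_genes_missing_in_train": len(missing_train),
        "selected_c": float(grid.selected[0]),
        "selected_sigma": float(grid.selected[1]),
        "cv_cindex": float(np.nanmax(grid.mean_cindex)),
        "test_cindex": float(cindex),
        "logrank_p": float(lr["p"]),
        "logrank_statistic": float(lr["statistic"]),
        "hr_high_vs_low": hr,
        "hr_ci": [ci_lo, ci_hi],
        "cox_p": cox_p,
        "rfs_3yr_low_risk": float(rfs3["low-risk"]),
        "rfs_3yr_high_risk": float(rfs3["high-risk"]),
        "ctx": ctx_report,
        "_scores": scores,
        "_groups": groups,
        "_model": model,
    }


def run_full_pipeline(config: RunConfig, bundle: dict | None = None) -> dict:
    """Execute every stage and return a JSON-serializable run report."""
    bundle = bundle or load_inputs(config)
    signature, sig_info = select_signature(bundle, config)
    if not signature:
        raise RuntimeError("derived signature is empty; nothing to train on")
    evaluation = evaluate_signature(bundle, config, signature)
    report = {
        "config": {
            "mode": config.mode,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "restart": config.restart,
            "cv_folds": config.cv_folds,
            "cv_repeats": config.cv_repeats,
            "reverse": config.reverse,
            "seed": config.seed,
            "synthetic": asdict(config.synthetic) if config.synthetic else None,
            "input_dir": config.input_dir,
        },
        "network": {
            "n_nodes": bundle["network"].n_nodes,
            "n_edges": bundle["network"].n_edges,
        },
        "signature": sig_info,
        "evaluation": {k: v for k, v in evaluation.items() if not k.startswith("_")},
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        pd.DataFrame({"score": evaluation["_scores"], "group": evaluation["_groups"]}) \
            .rename_axis("sample").to_csv(out / "risk_scores.tsv", sep="\t")
        (out / "signature_genes.txt").write_text("\n".join(sorted(signature)) + "\n")
    report["_signature"] = signature
    report["_evaluation_objects"] = {k: v for k, v in evaluation.items() if k.startswith("_")}
    return report


def run_mode_comparison(config: RunConfig, modes: tuple = MODES) -> pd.DataFrame:
    """All run modes on identical cohorts and seeds; one row per mode."""
    bundle = load_inputs(config)
    rows = []
    for mode in modes:
        cfg = _with(config, mode=mode, out_dir=None)
        try:
            rep = run_full_pipeline(cfg, bundle=bundle)
            rows.append({
                "mode": mode,
                "signature_size": rep["signature"]["signature_size"],
                "walk_executed": rep["signature"]["walk_executed"],
                "test_cindex": rep["evaluation"]["test_cindex"],
                "logrank_p": rep["evaluation"]["logrank_p"],
                "hr_high_vs_low": rep["evaluation"]["hr_high_vs_low"],
                "error": "",
            })
        except Exception as exc:  # per-mode failure recorded, comparison continues
            logger.warning("mode %s failed: %s", mode, exc)
            rows.append({"mode": mode, "signature_size": np.nan, "walk_executed": np.nan,
                         "test_cindex": np.nan, "logrank_p": np.nan,
                         "hr_high_vs_low": np.nan, "error": str(exc)})
    return pd.DataFrame(rows).set_index("mode")


def random_signature_baseline(config: RunConfig, n_sets: int = 10,
                              signature_size: int | None = None,
                              bundle: dict | None = None) -> dict:
    """Median test C-index / log-rank p over random same-size gene sets.

    The control for "any large gene set predicts outcome": each random
    set of matched size goes through the identical SSVM train/test
    procedure.
    """
    bundle = bundle or load_inputs(config)
    if signature_size is None:
        signature, _ = select_signature(bundle, config)
        signature_size = len(signature)
    genes = list(bundle["network"].nodes)
    base_seed = _stage_seed(config.seed, "baseline")
    cindexes, ps = [], []
    for k in range(n_sets):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, k]))
        random_set = set(rng.choice(genes, size=min(signature_size, len(genes)),
                                    replace=False))
        ev = evaluate_signature(bundle, config, random_set)
        cindexes.append(ev["test_cindex"])
        ps.append(ev["logrank_p"])
    return {
        "n_sets": n_sets,
        "signature_size": signature_size,
        "median_cindex": float(np.median(cindexes)),
        "median_logrank_p": float(np.median(ps)),
        "cindexes": [float(c) for c in cindexes],
        "logrank_ps": [float(p) for p in ps],
    }


def alpha_sweep(config: RunConfig, alphas: tuple = (0.005, 0.01, 0.05, 0.1)) -> pd.DataFrame:
    """Signature size and test performance across p-value cutoffs.

    The significance run is computed once; each alpha just re-thresholds
    it, so signature sizes are nested and non-decreasing in alpha.
    """
    if config.mode not in NETWORK_MODES:
        raise ValueError("alpha sweep requires a network mode (NEM/NE/NM)")
    bundle = load_inputs(config)
    sigs = bundle["signatures"] if config.mode in ("NEM", "NE") else None
    muts = bundle["mutations"] if config.mode in ("NEM", "NM") else None
    result, _ = run_prioritization(
        bundle["network"], sigs, muts, mode=config.mode, alpha=config.alpha,
        n_perm=config.n_perm, seed=_stage_seed(config.seed, "permutations"),
        r=config.restart,
    )
    rows = []
    for alpha in sorted(alphas):
        genes = set(result.significant(alpha))
        row = {"alpha": alpha, "signature_size": len(genes)}
        if not genes:
            row.update(test_cindex=np.nan, logrank_p=np.nan, status="untrainable")
        else:
            try:
                ev = evaluate_signature(bundle, config, genes)
                row.update(test_cindex=ev["test_cindex"], logrank_p=ev["logrank_p"],
                           status="ok")
            except Exception as exc:
                row.update(test_cindex=np.nan, logrank_p=np.nan, status=str(exc))
        rows.append(row)
    return pd.DataFrame(rows).set_index("alpha")


def robustness_leave_one_out(config: RunConfig, bundle: dict | None = None) -> dict:
    """Leave-one-signature-out Dice robustness on this run's inputs."""
    bundle = bundle or load_inputs(config)
    return leave_one_signature_out(
        bundle["network"], bundle["signatures"], bundle["mutations"],
        alpha=config.alpha, n_perm=config.n_perm,
        seed=_stage_seed(config.seed, "permutations"), mode=config.mode,
    )


def _with(config: RunConfig, **overrides) -> RunConfig:
    data = {
        "input_dir": config.input_dir,
        "synthetic": config.synthetic,
        "mode": config.mode,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "restart": config.restart,
        "c_values": config.c_values,
        "sigma_values": config.sigma_values,
        "cv_folds": config.cv_folds,
        "cv_repeats": config.cv_repeats,
        "reverse": config.reverse,
        "seed": config.seed,
        "out_dir": config.out_dir,
    }
    data.update(overrides)
    return RunConfig(**data)
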