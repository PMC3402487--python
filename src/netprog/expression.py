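"""Expression-matrix preparation and clinical annotation handling.

Matrices are pandas DataFrames with genes (or probes) in rows and samples
in columns. Preparation follows the usual microarray post-processing
chain: probes mapping to several genes are discarded, multiple probes for
one gene are collapsed to the probe with the largest interquartile range,
and each gene row is Z-scored so expression levels are comparable across
genes. Train and test cohorts are always standardized separately to keep
them independent.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_probesets",
    "zscore_genes",
    "subset_to_signature",
    "read_expression",
    "read_clinical",
    "validate_clinical",
]

CLINICAL_COLUMNS = ["time", "event", "stage", "age", "gender", "ctx"]


def collapse_probesets(values: pd.DataFrame, probe_to_gene: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-by-sample matrix to gene-by-sample.

    ``probe_to_gene`` has two columns (probe, gene) and may be many-to-many.
    Probes mapped to more than one gene are eliminated; when several probes
    map to one gene the probe with the largest IQR across samples wins
    (linear-interpolation quartiles; IQR ties broken by lexicographic probe
    ID for determinism).
    """
    mapping = probe_to_gene.iloc[:, :2].copy()
    mapping.columns = ["probe", "gene"]
    mapping = mapping.drop_duplicates()
    multi = mapping.groupby("probe")["gene"].nunique()
    ambiguous = set(multi[multi > 1].index)
    mapping = mapping[~mapping["probe"].isin(ambiguous)]
    mapping = mapping[mapping["probe"].isin(values.index)]
    if mapping.empty:
        raise ValueError("no probes left after removing multi-gene probes")

    q75 = values.quantile(0.75, axis=1)
    q25 = values.quantile(0.25, axis=1)
    iqr = (q75 - q25).astype(float)

    rows: dict[str, str] = {}
    for gene, grp in mapping.groupby("gene"):
        probes = sorted(grp["probe"])
        # argmax over the sorted list keeps the lexicographically smallest
        # probe among IQR ties — deterministic across runs
        rows[gene] = probes[int(np.argmax([iqr[p] for p in probes]))]
    genes = sorted(rows)
    out = values.loc[[rows[g] for g in genes]].copy()
    out.index = genes
    return out


def zscore_genes(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Row-standardize: per gene subtract the mean, divide by the SD.

    Population SD (ddof=0) by default. Constant genes (SD 0) are dropped
    with a warning; if everything is constant that is an error.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.all():
        raise ValueError("all genes are constant; nothing to standardize")
    if constant.any():
        logger.warning("dropping %d constant gene(s) before Z-scoring", int(constant.sum()))
    keep = ~constant
    z = (vals[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def subset_to_signature(matrix: pd.DataFrame, signature: set[str]) -> tuple[pd.DataFrame, list[str]]:
    """Restrict rows to signature genes present in the matrix.

    Returns the restricted matrix (rows in lexicographic signature order)
    and the sorted list of signature genes that are not measured.
    """
    present = sorted(set(signature) & set(matrix.index))
    missing = sorted(set(signature) - set(matrix.index))
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    if missing:
        logger.info("%d signature gene(s) missing from the expression matrix", len(missing))
    return matrix.loc[present].copy(), missing


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample TSV with a header row of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df.astype(float)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV indexed by sample, 'NA' for missing adjuvant-CTX."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = df.copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event flag must be 0/1")
    bad_stage = set(df["stage"].unique()) - {"II", "III"}
    if bad_stage:
        raise ValueError(f"stage must be II or III (stage I/IV excluded upstream): {bad_stage}")
    return df
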