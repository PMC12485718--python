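"""Cell- and gene-level quality-control filters for droplet scRNA-seq.

The cell filters follow the two-pass scheme used for the gastruloid data:
an initial pass removing cells with fewer than 1,000 UMIs or fewer than 500
detected genes, then a second pass removing cells with fewer than 5,000 UMIs,
cells in the top 0.1% by UMI total, doublet scores over 0.2, MT% over 10 or
Ribo% over 40. All inequalities are strict, so a boundary value (exactly
5,000 UMIs, doublet score exactly 0.2) is retained. The top-0.1% rule is a
cell-count rule: it removes the ceil(f*N) highest-UMI cells of the population
entering its pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellQCWarning",
    "FilterReport",
    "DEFAULT_PASSES",
    "compute_cell_qc",
    "apply_gene_filters",
    "evaluate_rules",
    "apply_cell_filters",
    "flag_doublet_clusters",
]


class CellQCWarning(UserWarning):
    pass


@dataclass
class FilterReport:
    rule: str
    n_removed: int
    n_retained: int


# rule -> (column, kind); "min"/"max" are strict boundaries, "top_frac" is
# the cell-count rule on umi_total.
_RULES = {
    "umi_min": ("umi_total", "min"),
    "genes_min": ("genes_detected", "min"),
    "doublet_max": ("doublet_score", "max"),
    "mt_max": ("mt_pct", "max"),
    "ribo_max": ("ribo_pct", "max"),
    "umi_top_frac": ("umi_total", "top_frac"),
}

DEFAULT_PASSES: list[list[tuple[str, float]]] = [
    [("umi_min", 1000), ("genes_min", 500)],
    [("umi_min", 5000), ("umi_top_frac", 0.001), ("doublet_max", 0.2),
     ("mt_max", 10.0), ("ribo_max", 40.0)],
]


def compute_cell_qc(adata: AnnData) -> pd.DataFrame:
    """Per-cell QC table: UMI total, detected genes, MT% and Ribo%.

    Requires boolean ``mt`` and ``ribo`` columns in ``adata.var``. All-zero
    cells get MT%/Ribo% of 0 and a ``zero_total`` flag.
    """
    for col in ("mt", "ribo"):
        if col not in adata.var:
            raise ValueError(f"adata.var must contain a boolean '{col}' column")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.tocsr()
    umi = np.asarray(X.sum(axis=1)).ravel()
    genes = X.getnnz(axis=1)
    mt_umi = np.asarray(X[:, adata.var["mt"].to_numpy()].sum(axis=1)).ravel()
    ribo_umi = np.asarray(X[:, adata.var["ribo"].to_numpy()].sum(axis=1)).ravel()

    zero = umi == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero UMIs; MT%/Ribo% set to 0",
            CellQCWarning,
        )
    denom = np.where(zero, 1.0, umi.astype(float))
    qc = pd.DataFrame(
        {
            "umi_total": umi.astype(int),
            "genes_detected": genes.astype(int),
            "mt_pct": 100.0 * mt_umi / denom,
            "ribo_pct": 100.0 * ribo_umi / denom,
            "zero_total": zero,
        },
        index=adata.obs_names,
    )
    if "doublet_score" in adata.obs:
        qc["doublet_score"] = adata.obs["doublet_score"].to_numpy()
    qc.index.name = "cell_id"
    return qc


def apply_gene_filters(adata: AnnData, stage: str) -> AnnData:
    """Gene retention rules.

    stage="primary": keep genes on chromosomes 1-22, X, Y and MT.
    stage="embedding": keep protein_coding and lincRNA biotypes, drop X/Y.
    """
    chrom = adata.var["chromosome"].astype(str)
    if stage == "primary":
        allowed = {str(c) for c in range(1, 23)} | {"X", "Y", "MT"}
        keep = chrom.isin(allowed)
    elif stage == "embedding":
        keep = adata.var["biotype"].isin(["protein_coding", "lincRNA"]) & ~chrom.isin(
            ["X", "Y"]
        )
    else:
        raise ValueError(f"unknown gene-filter stage {stage!r}")
    return adata[:, keep.to_numpy()].copy()


def _rule_pass(qc: pd.DataFrame, rule: str, param: float) -> pd.Series:
    """Boolean pass vector for one conjunctive rule (strict inequalities)."""
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}")
    col, kind = _RULES[rule]
    if kind == "min":
        return qc[col] >= param  # removed iff strictly fewer than param
    if kind == "max":
        return qc[col] <= param  # removed iff strictly over param
    # top_frac: remove the ceil(param*N) highest-UMI cells; ties broken by
    # input order, later rows removed first.
    n = len(qc)
    m = int(np.ceil(param * n))
    if m <= 0:
        return pd.Series(True, index=qc.index)
    umi = qc[col].to_numpy()
    pos = np.arange(n)
    order = np.lexsort((-pos, -umi))  # by umi desc, then later rows first
    out = np.ones(n, dtype=bool)
    out[order[:m]] = False
    return pd.Series(out, index=qc.index)


def evaluate_rules(
    qc: pd.DataFrame, rules: list[tuple[str, float]]
) -> pd.DataFrame:
    """Per-rule pass booleans evaluated jointly on the given population."""
    return pd.DataFrame(
        {f"{rule}({param})": _rule_pass(qc, rule, param) for rule, param in rules}
    )


def apply_cell_filters(
    qc: pd.DataFrame,
    passes: list[list[tuple[str, float]]] | None = None,
) -> tuple[pd.Index, list[FilterReport]]:
    """Sequential conjunctive filter passes; returns retained ids + reports.

    Within a pass all rules are conjunctive (order-invariant); the
    ``umi_top_frac`` rule is evaluated on the population entering its pass.
    """
    if len(qc) == 0:
        raise ValueError("empty QC table")
    if passes is None:
        passes = DEFAULT_PASSES
    current = qc
    reports: list[FilterReport] = []
    for rules in passes:
        flags = evaluate_rules(current, rules)
        for colname in flags.columns:
            ok = flags[colname]
            reports.append(
                FilterReport(
                    rule=colname,
                    n_removed=int((~ok).sum()),
                    n_retained=int(ok.sum()),
                )
            )
        current = current[flags.all(axis=1)]
    if len(current) == 0:
        warnings.warn("all cells removed by filters", CellQCWarning)
    return current.index, reports


def flag_doublet_clusters(
    qc: pd.DataFrame,
    cluster_labels: pd.Series | np.ndarray,
    score_factor: float = 2.0,
) -> list:
    """Clusters whose mean doublet score exceeds score_factor x the median
    of per-cluster mean scores."""
    labels = pd.Series(np.asarray(cluster_labels), index=qc.index, name="cluster")
    means = qc["doublet_score"].groupby(labels).mean()
    if len(means) < 2:
        warnings.warn("fewer than 2 clusters; nothing flagged", CellQCWarning)
        return []
    cutoff = score_factor * means.median()
    return sorted(means.index[means > cutoff].tolist())
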