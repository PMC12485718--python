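"""Reciprocal NNLS cell-type correspondence between two datasets.

For each target cluster profile T_a in dataset A, non-negative least squares
predicts T_a from all cluster profiles M_b of dataset B with a free
intercept: T_a = b0 + M_b @ beta, beta >= 0. The regression is restricted to
the union of the most highly expressed and most highly specific genes of the
target cluster. The roles of A and B are then switched, and the two directed
coefficients for a cluster pair (a, b) are combined into a symmetric
statistic beta = 2 (beta_ab + 0.01)(beta_ba + 0.01); high values indicate
reciprocal, specific predictivity. Rows of the combined matrix are scaled by
their maxima for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import LogNormalizer, _as_dense

__all__ = [
    "ClusterProfile",
    "NNLSRegressor",
    "ReciprocalCorrespondence",
    "CorrespondenceResult",
    "pseudobulk_profiles",
    "select_genes_for_target",
    "nnls_fit",
    "combine_betas",
    "correspondence_matrix",
    "map_homologs",
]

EPSILON_SPECIFICITY = 1e-8
BETA_OFFSET = 0.01


@dataclass
class ClusterProfile:
    """Cluster x gene matrix of mean log-normalized expression."""

    profiles: pd.DataFrame
    n_cells: pd.Series
    downsample_n: int | None = None
    seed: int = 0


def pseudobulk_profiles(
    norm: AnnData,
    cluster_labels,
    downsample_n: int | None = None,
    seed: int = 0,
) -> ClusterProfile:
    """Per-cluster mean log-normalized expression, optionally downsampled.

    Clusters larger than ``downsample_n`` are subsampled without replacement
    before averaging (one seeded draw per cluster, in sorted label order);
    smaller clusters are used whole.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=norm.obs_names)
    X = _as_dense(norm.X)
    rng = np.random.default_rng(seed)
    rows = {}
    n_cells = {}
    for lab in sorted(labels.unique(), key=str):
        idx = np.flatnonzero((labels == lab).to_numpy())
        if idx.size == 0:
            raise ValueError(f"empty cluster {lab!r}")
        if downsample_n is not None and idx.size > downsample_n:
            idx = rng.choice(idx, size=downsample_n, replace=False)
        rows[lab] = X[idx].mean(axis=0)
        n_cells[lab] = idx.size
    profiles = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=norm.var_names)
    return ClusterProfile(
        profiles=profiles,
        n_cells=pd.Series(n_cells),
        downsample_n=downsample_n,
        seed=seed,
    )


def select_genes_for_target(
    target: pd.Series,
    all_profiles: ClusterProfile | pd.DataFrame,
    n_expr: int = 1500,
    n_spec: int = 1500,
) -> pd.Index:
    """Union of the top ``n_expr`` expressed and top ``n_spec`` specific genes.

    Specificity(g) = target(g) / (mean over all clusters of profile(g) +
    1e-8); genes not expressed in the target are excluded from the
    specificity ranking. Ties break by gene order.
    """
    profs = all_profiles.profiles if isinstance(all_profiles, ClusterProfile) else all_profiles
    if len(target) < 1:
        raise ValueError("empty gene universe")
    t = target.to_numpy(dtype=float)
    pos = np.arange(len(t))

    expr_order = np.lexsort((pos, -t))
    top_expr = expr_order[: min(n_expr, len(t))]

    spec = t / (profs.to_numpy(dtype=float).mean(axis=0) + EPSILON_SPECIFICITY)
    spec = np.where(t > 0, spec, -np.inf)
    spec_order = np.lexsort((pos, -spec))
    n_eligible = int((t > 0).sum())
    top_spec = spec_order[: min(n_spec, n_eligible)]

    sel = np.zeros(len(t), dtype=bool)
    sel[top_expr] = True
    sel[top_spec] = True
    return target.index[sel]


class NNLSRegressor(RegressorMixin, BaseEstimator):
    """Non-negative least squares with an unconstrained intercept.

    Solves min ||y - (b0 + X @ beta)||_2 with beta >= 0 and b0 free, by
    augmenting the design with +1 and -1 constant columns inside a single
    NNLS solve (b0 = b_plus - b_minus).
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in NNLS inputs")
        n, p = X.shape
        if self.fit_intercept:
            A = np.column_stack([X, np.ones(n), -np.ones(n)])
        else:
            A = X
        coef, _ = scipy.optimize.nnls(A, y)
        if self.fit_intercept:
            self.coef_ = coef[:p]
            self.intercept_ = float(coef[p] - coef[p + 1])
        else:
            self.coef_ = coef
            self.intercept_ = 0.0
        resid = y - (X @ self.coef_ + self.intercept_)
        self.residual_norm_ = float(np.linalg.norm(resid))
        self.n_features_in_ = p
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


@dataclass
class NNLSFit:
    beta0: float
    beta: np.ndarray
    residual_norm: float
    gene_set_size: int


def nnls_fit(target: np.ndarray, design: np.ndarray) -> NNLSFit:
    """NNLS of ``target`` on the columns of ``design`` with free intercept."""
    reg = NNLSRegressor().fit(np.asarray(design, dtype=float),
                              np.asarray(target, dtype=float))
    return NNLSFit(
        beta0=reg.intercept_,
        beta=reg.coef_,
        residual_norm=reg.residual_norm_,
        gene_set_size=len(np.asarray(target)),
    )


def combine_betas(beta_ab: float, beta_ba: float) -> float:
    """Symmetric reciprocal statistic 2(beta_ab + 0.01)(beta_ba + 0.01)."""
    if beta_ab < 0 or beta_ba < 0:
        raise ValueError("directed coefficients must be non-negative")
    return 2.0 * (beta_ab + BETA_OFFSET) * (beta_ba + BETA_OFFSET)


@dataclass
class CorrespondenceResult:
    beta_ab: pd.DataFrame  # A-targets x B-clusters
    beta_ba: pd.DataFrame  # B-targets x A-clusters
    combined: pd.DataFrame  # A x B
    row_scaled: pd.DataFrame  # A x B, each row / its max
    gene_set_sizes: dict = field(default_factory=dict)


class ReciprocalCorrespondence(BaseEstimator):
    """Reciprocal NNLS correspondence between two sets of cluster profiles.

    ``fit(profiles_a, profiles_b)`` restricts both profile sets to their
    shared gene universe, runs the directed NNLS in both directions with
    per-target gene selection, and exposes ``beta_ab_``, ``beta_ba_``,
    ``combined_`` and ``row_scaled_`` DataFrames. ``row_scale="max"``
    divides each combined row by its maximum; ``"z"`` z-scores rows.
    """

    def __init__(self, n_expr: int = 1500, n_spec: int = 1500,
                 row_scale: str = "max"):
        self.n_expr = n_expr
        self.n_spec = n_spec
        self.row_scale = row_scale

    @staticmethod
    def _directed(
        targets: pd.DataFrame, design: pd.DataFrame, n_expr: int, n_spec: int
    ) -> tuple[pd.DataFrame, dict]:
        betas = pd.DataFrame(
            0.0, index=targets.index, columns=design.index, dtype=float
        )
        sizes = {}
        for a in targets.index:
            genes = select_genes_for_target(
                targets.loc[a], targets, n_expr=n_expr, n_spec=n_spec
            )
            fit = nnls_fit(
                targets.loc[a, genes].to_numpy(),
                design[genes].to_numpy().T,
            )
            betas.loc[a] = fit.beta
            sizes[a] = len(genes)
        return betas, sizes

    def fit(self, profiles_a: ClusterProfile, profiles_b: ClusterProfile):
        pa = profiles_a.profiles if isinstance(profiles_a, ClusterProfile) else profiles_a
        pb = profiles_b.profiles if isinstance(profiles_b, ClusterProfile) else profiles_b
        if len(pa) < 2 or len(pb) < 2:
            raise ValueError("need at least 2 clusters per dataset")
        shared = pa.columns.intersection(pb.columns)
        if len(shared) == 0:
            raise ValueError("empty shared gene universe")
        pa = pa[shared]
        pb = pb[shared]

        beta_ab, sizes_a = self._directed(pa, pb, self.n_expr, self.n_spec)
        beta_ba, sizes_b = self._directed(pb, pa, self.n_expr, self.n_spec)

        combined = pd.DataFrame(
            2.0 * (beta_ab.to_numpy() + BETA_OFFSET)
            * (beta_ba.to_numpy().T + BETA_OFFSET),
            index=beta_ab.index,
            columns=beta_ab.columns,
        )
        if self.row_scale == "max":
            row_scaled = combined.div(combined.max(axis=1), axis=0)
        elif self.row_scale == "z":
            row_scaled = combined.sub(combined.mean(axis=1), axis=0).div(
                combined.std(axis=1, ddof=1), axis=0
            )
        else:
            raise ValueError(f"unknown row_scale {self.row_scale!r}")
        self.beta_ab_ = beta_ab
        self.beta_ba_ = beta_ba
        self.combined_ = combined
        self.row_scaled_ = row_scaled
        self.gene_set_sizes_ = {"A": sizes_a, "B": sizes_b}
        return self


def correspondence_matrix(
    profiles_a: ClusterProfile,
    profiles_b: ClusterProfile,
    n_expr: int = 1500,
    n_spec: int = 1500,
) -> CorrespondenceResult:
    est = ReciprocalCorrespondence(n_expr=n_expr, n_spec=n_spec).fit(
        profiles_a, profiles_b
    )
    return CorrespondenceResult(
        beta_ab=est.beta_ab_,
        beta_ba=est.beta_ba_,
        combined=est.combined_,
        row_scaled=est.row_scaled_,
        gene_set_sizes=est.gene_set_sizes_,
    )


def map_homologs(counts: AnnData, homolog_table: pd.DataFrame) -> AnnData:
    """Collapse counts onto homologous target genes and re-log-normalize.

    ``homolog_table`` has two columns (source id, target id) and may be
    many-to-many: each target gene's count is the sum of all its mapped
    source genes' counts. The collapsed counts are then log-normalized.
    """
    if len(homolog_table) == 0:
        raise ValueError("empty homolog mapping")
    src = homolog_table.iloc[:, 0].astype(str)
    tgt = homolog_table.iloc[:, 1].astype(str)
    keep = src.isin(counts.var_names)
    src, tgt = src[keep], tgt[keep]
    if len(src) == 0:
        raise ValueError("no homolog source genes present in the matrix")
    targets = pd.Index(sorted(tgt.unique()))
    src_pos = counts.var_names.get_indexer(src)
    tgt_pos = targets.get_indexer(tgt)
    # genes x targets indicator for the count collapse
    M = sp.csr_matrix(
        (np.ones(len(src)), (src_pos, tgt_pos)),
        shape=(counts.n_vars, len(targets)),
    )
    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)
    collapsed = (X @ M).tocsr()
    out = AnnData(
        X=collapsed,
        obs=counts.obs.copy(),
        var=pd.DataFrame(index=targets),
    )
    out.var.index.name = "gene_id"
    norm = LogNormalizer().fit(out.X).transform(out.X)
    out.layers["counts"] = out.X.copy()
    out.X = norm
    return out
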