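"""Normalization, feature selection, covariate regression, PCA, clustering.

Estimator classes follow the scikit-learn contract (``fit`` / ``transform``,
fitted attributes with trailing underscores, ``get_params``/``set_params``)
and operate on cells-x-genes matrices; thin functions adapt them to AnnData.

Pipeline convention, matching the toolkit defaults the analyses assume:
log1p(10,000 x count / cell total) normalization; highly-variable genes by
binned standardized dispersion; per-gene OLS residualization against
covariates (e.g. a cell-cycle score) followed by standardization; exact-SVD
PCA with a deterministic sign convention; modularity community detection on
a kNN graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LogNormalizer",
    "HVGSelector",
    "ScaleRegressor",
    "PCAEmbedder",
    "GraphClusterer",
    "Embedding",
    "lognormalize",
    "select_hvg",
    "module_score",
    "scale_and_regress",
    "pca",
    "neighbor_graph_cluster",
]

SCALE_FACTOR = 10_000.0


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X, dtype=float)


class LogNormalizer(TransformerMixin, BaseEstimator):
    """log1p(scale_factor * count / cell_total) normalization.

    Stateless; ``fit`` only validates. Cells with zero totals are an error:
    they must be removed by QC first.
    """

    def __init__(self, scale_factor: float = SCALE_FACTOR):
        self.scale_factor = scale_factor

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if sp.issparse(X):
            X = X.tocsr().astype(float)
            totals = np.asarray(X.sum(axis=1)).ravel()
            if np.any(totals == 0):
                raise ValueError("zero-total cell: apply QC filtering first")
            out = X.multiply(self.scale_factor / totals[:, None]).tocsr()
            out.data = np.log1p(out.data)
            return out
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("zero-total cell: apply QC filtering first")
        return np.log1p(self.scale_factor * X / totals[:, None])


class HVGSelector(TransformerMixin, BaseEstimator):
    """Highly variable genes by variance-stabilized dispersion.

    On the expm1 of log-normalized values, fits a lowess trend of
    log10(variance) on log10(mean) across genes, standardizes each gene's
    values by the trend-expected standard deviation (clipped at
    sqrt(n_cells)) and ranks genes by the variance of the standardized
    values. Never-expressed and constant genes get a standardized variance
    of 0 and can never outrank a variable gene; ties break by gene order.
    Deterministic given the input.
    """

    def __init__(self, n_top: int = 2500, lowess_frac: float = 0.3):
        self.n_top = n_top
        self.lowess_frac = lowess_frac

    def fit(self, X, y=None):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        Xd = _as_dense(X)
        n_cells, n_genes = Xd.shape
        if self.n_top > n_genes:
            raise ValueError("n_top exceeds the number of genes")
        E = np.expm1(Xd)
        mean = E.mean(axis=0)
        var = E.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
        pos = (mean > 0) & (var > 0)

        std_var = np.zeros(n_genes)
        if pos.sum() >= 2:
            fit = lowess(
                np.log10(var[pos]), np.log10(mean[pos]),
                frac=self.lowess_frac, return_sorted=False,
            )
            sd_expected = np.sqrt(np.power(10.0, fit))
            clip = np.sqrt(n_cells)
            Z = np.clip((E[:, pos] - mean[pos]) / sd_expected, -clip, clip)
            std_var[pos] = Z.var(axis=0, ddof=1)
        elif pos.any():
            std_var[pos] = 1.0

        rank = np.lexsort((np.arange(n_genes), -std_var))
        sel = np.zeros(n_genes, dtype=bool)
        sel[rank[: self.n_top]] = True
        self.means_ = mean
        self.variances_ = var
        self.dispersions_norm_ = std_var
        self.highly_variable_ = sel
        self.n_features_in_ = n_genes
        return self

    def transform(self, X):
        return X[:, self.highly_variable_]


class ScaleRegressor(TransformerMixin, BaseEstimator):
    """Per-gene OLS residualization against covariates, then standardize.

    For each gene, fits expression ~ intercept + covariates by ordinary
    least squares, takes residuals, and standardizes them to mean 0 /
    sd 1 (ddof=``ddof``). Genes with zero residual variance are emitted as
    all-zero rows and flagged in ``zero_variance_``.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None, covariates: np.ndarray | None = None):
        self.covariates_ = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != X.shape[0]:
                C = C.T
            if C.shape[0] != X.shape[0]:
                raise ValueError("covariate length does not match cell count")
            if not np.all(np.isfinite(C)):
                raise ValueError("covariates must be finite")
            if np.any(C.std(axis=0) == 0):
                raise ValueError("covariate is collinear with the intercept")
            self.covariates_ = C
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        Xd = _as_dense(X)
        n = Xd.shape[0]
        if self.covariates_ is not None:
            D = np.column_stack([np.ones(n), self.covariates_])
            beta, *_ = np.linalg.lstsq(D, Xd, rcond=None)
            R = Xd - D @ beta
        else:
            R = Xd - Xd.mean(axis=0)
        sd = R.std(axis=0, ddof=self.ddof)
        zero = sd <= 1e-12
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} gene(s) with zero residual variance "
                "set to all-zero rows"
            )
        out = np.zeros_like(R)
        nz = ~zero
        out[:, nz] = (R[:, nz] - R[:, nz].mean(axis=0)) / sd[nz]
        self.zero_variance_ = zero
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


@dataclass
class Embedding:
    """Cell coordinates in PC space with loadings and annotations."""

    coordinates: pd.DataFrame  # cells x PCs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x PCs
    labels: pd.DataFrame  # per-cell annotations (dataset/stage/type)


class PCAEmbedder(TransformerMixin, BaseEstimator):
    """Exact-SVD PCA with a deterministic sign convention.

    Each component is oriented so that its largest-magnitude loading entry
    is positive, which removes the SVD sign ambiguity. Requesting more
    components than the matrix rank is an error.
    """

    def __init__(self, n_comps: int = 30):
        self.n_comps = n_comps

    def fit(self, X, y=None):
        Xd = _as_dense(X)
        if self.n_comps > min(Xd.shape):
            raise ValueError("n_comps exceeds min(n_cells, n_genes)")
        p = PCA(n_components=self.n_comps, svd_solver="full")
        p.fit(Xd)
        s = p.singular_values_
        # rank of the uncentered data bounds the usable components; centering
        # can drop it by at most one, hence the +1 allowance
        rank_centered = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
        if self.n_comps > rank_centered + 1:
            raise ValueError("n_comps exceeds the rank of the data")
        comp = p.components_.copy()
        flip = np.sign(comp[np.arange(comp.shape[0]),
                            np.argmax(np.abs(comp), axis=1)])
        comp *= flip[:, None]
        self.components_ = comp
        self.mean_ = p.mean_
        self.explained_variance_ = p.explained_variance_
        self.explained_variance_ratio_ = p.explained_variance_ratio_
        self.n_features_in_ = Xd.shape[1]
        return self

    def transform(self, X):
        Xd = _as_dense(X)
        return (Xd - self.mean_) @ self.components_.T


class GraphClusterer(BaseEstimator):
    """Community detection on a kNN graph in embedding space.

    Builds a k-nearest-neighbor graph (Euclidean) and partitions it with
    modularity-based community detection (RB-configuration partition, which
    reduces to Louvain-style modularity at resolution 1). Deterministic
    given ``seed``.
    """

    def __init__(self, n_neighbors: int = 15, resolution: float = 1.0,
                 seed: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit_predict(self, X, y=None):
        import igraph as ig
        import leidenalg

        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_neighbors <= 0:
            raise ValueError("n_neighbors must be positive")
        k = min(self.n_neighbors, n - 1)
        if k == 0:
            self.labels_ = np.zeros(n, dtype=int)
            return self.labels_
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        edges = {
            (min(i, j), max(i, j))
            for i in range(n)
            for j in idx[i]
            if i != j  # with coincident points, self may appear anywhere
        }
        # coincident points are mutual neighbors regardless of kNN tie-breaks
        _, inverse, counts = np.unique(
            X, axis=0, return_inverse=True, return_counts=True
        )
        for g in np.flatnonzero(counts > 1):
            members = np.flatnonzero(inverse == g)
            edges.update(
                (int(a), int(b))
                for i, a in enumerate(members)
                for b in members[i + 1:]
            )
        g = ig.Graph(n=n, edges=sorted(edges))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=self.seed,
        )
        self.labels_ = np.asarray(part.membership, dtype=int)
        return self.labels_


# ---------------------------------------------------------------------------
# AnnData-facing wrappers
# ---------------------------------------------------------------------------

def lognormalize(adata: AnnData, scale_factor: float = SCALE_FACTOR) -> AnnData:
    """Return a copy with log-normalized X; raw counts kept in layer 'counts'."""
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = LogNormalizer(scale_factor).fit(adata.X).transform(adata.X)
    out.uns["scale_factor"] = scale_factor
    return out


def select_hvg(norm: AnnData, n: int = 2500) -> pd.Index:
    sel = HVGSelector(n_top=n).fit(norm.X)
    norm.var["highly_variable"] = sel.highly_variable_
    norm.var["dispersions_norm"] = sel.dispersions_norm_
    return norm.var_names[sel.highly_variable_]


def module_score(
    norm: AnnData,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched module score (mean over set minus matched controls).

    Genes are binned into ``n_bins`` equal-frequency bins of mean
    expression; each set gene contributes ``n_ctrl`` control genes sampled
    (with replacement if needed) from its own bin. Reconstruction of the
    usual cell-cycle scoring convention.
    """
    genes = pd.Index(gene_set)
    present = genes.intersection(norm.var_names)
    if len(present) == 0:
        raise ValueError("gene_set has no genes in the matrix")
    X = _as_dense(norm.X)
    var_names = norm.var_names
    mean = X.mean(axis=0)
    n_genes = X.shape[1]
    order = np.argsort(mean, kind="stable")
    bin_id = np.empty(n_genes, dtype=int)
    bin_id[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    rng = np.random.default_rng(seed)
    set_idx = var_names.get_indexer(present)
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bin_id == bin_id[gi]) & ~in_set)
        if pool.size == 0:  # set saturates the bin; fall back to all others
            pool = np.flatnonzero(~in_set)
        if pool.size == 0:  # set is the whole matrix; score against itself
            pool = set_idx
        take = rng.choice(pool, size=min(n_ctrl, pool.size), replace=False)
        ctrl_idx.append(take)
    ctrl = np.unique(np.concatenate(ctrl_idx))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)


def scale_and_regress(
    norm: AnnData,
    genes=None,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Scaled (and optionally covariate-regressed) cells-x-genes matrix."""
    sub = norm if genes is None else norm[:, pd.Index(genes)]
    return ScaleRegressor().fit_transform(sub.X, covariates=covariates)


def pca(scaled: np.ndarray, d: int = 30, index=None, labels=None) -> Embedding:
    emb = PCAEmbedder(n_comps=d).fit(scaled)
    coords = emb.transform(scaled)
    idx = index if index is not None else pd.RangeIndex(scaled.shape[0])
    cols = [f"PC{i + 1}" for i in range(d)]
    return Embedding(
        coordinates=pd.DataFrame(coords, index=idx, columns=cols),
        explained_variance=emb.explained_variance_,
        explained_variance_ratio=emb.explained_variance_ratio_,
        loadings=pd.DataFrame(emb.components_.T, columns=cols),
        labels=pd.DataFrame(index=idx) if labels is None else labels.copy(),
    )


def neighbor_graph_cluster(
    embedding: Embedding, k: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    return GraphClusterer(n_neighbors=k, resolution=resolution, seed=seed).fit_predict(
        embedding.coordinates.to_numpy()
    )
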