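"""Small defined analyses: PC1 axis genes, HOX qPCR normalization,
line-of-origin composition.

``axis_pc1_analysis`` re-embeds a cell subset (e.g. the four neural-tube
cell types) with its own HVG/scale/PCA and ranks every gene by Pearson
correlation with PC1, with Benjamini-Hochberg adjusted p-values — the
procedure behind the anterior/posterior neural-tube axis interpretation.

``hox_qpcr_normalize`` converts Ct values to relative expression against a
housekeeping gene (2^-dCt by default) and z-scores each gene across the
dissected segments (anterior/middle/posterior).

``line_composition`` tabulates, per cell type, the fraction of cells
assigned to each donor line (plus doublet/unassigned), with an optional
confident-only view renormalized over the two lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from anndata import AnnData
from statsmodels.stats.multitest import multipletests

from .preprocess import HVGSelector, PCAEmbedder, ScaleRegressor, _as_dense

__all__ = [
    "AxisAnalysis",
    "axis_pc1_analysis",
    "hox_qpcr_normalize",
    "line_composition",
]


@dataclass
class AxisAnalysis:
    pc_scores: pd.DataFrame  # cells x first 3 PCs
    variance_fraction: np.ndarray  # per-PC fraction of total variance
    gene_correlations: pd.DataFrame  # r, p, q, zero_variance per gene


def _pearson_vs_vector(X: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r of X against v; zero-variance columns get r=0."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    sx = Xc.std(axis=0)
    sv = vc.std()
    zero = (sx == 0) | (sv == 0)
    denom = np.where(zero, 1.0, sx * sv) * n
    r = (Xc * vc[:, None]).sum(axis=0) / denom
    r = np.clip(np.where(zero, 0.0, r), -1.0, 1.0)
    return r, zero


def axis_pc1_analysis(
    norm: AnnData,
    cell_subset,
    n_hvg: int = 2500,
    d: int = 30,
) -> AxisAnalysis:
    """PCA of a cell subset plus per-gene correlation with PC1.

    The embedding uses the subset's own HVGs; the correlation ranking uses
    all genes of the log-normalized matrix. p-values come from the
    t-transform of r with n-2 degrees of freedom, adjusted by
    Benjamini-Hochberg. Constant genes are reported with r=0 and flagged.
    """
    subset = pd.Index(cell_subset)
    if len(subset) == 0:
        raise ValueError("empty cell subset")
    sub = norm[subset]
    X = _as_dense(sub.X)
    n = X.shape[0]
    if n < d + 1:
        raise ValueError("cell subset smaller than d + 1")

    hvg = HVGSelector(n_top=min(n_hvg, X.shape[1])).fit(X)
    Xs = ScaleRegressor().fit_transform(hvg.transform(X))
    emb = PCAEmbedder(n_comps=d).fit(Xs)
    coords = emb.transform(Xs)
    pc1 = coords[:, 0]

    r, zero = _pearson_vs_vector(X, pc1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(zero, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    genes = pd.DataFrame(
        {"r": r, "p": p, "q": q, "zero_variance": zero},
        index=sub.var_names,
    )
    return AxisAnalysis(
        pc_scores=pd.DataFrame(
            coords[:, :3], index=subset, columns=["PC1", "PC2", "PC3"]
        ),
        variance_fraction=emb.explained_variance_ratio_,
        gene_correlations=genes.sort_values("r", ascending=False),
    )


def hox_qpcr_normalize(
    ct: pd.DataFrame,
    reference_gene: str = "GAPDH",
    transform: str = "power2",
) -> pd.DataFrame:
    """Housekeeping-normalized, across-segment z-scored qPCR expression.

    ``ct`` is a gene x segment table of Ct values (NaN = not detected).
    Relative expression is 2^-(Ct_gene - Ct_ref) per segment (``transform=
    "linear"`` uses the raw -dCt instead); each gene row is then z-scored
    across segments (sample sd). Genes undetected in any segment come back
    as all-NaN rows; zero-sd rows come back as zeros, flagged in
    ``attrs['zero_sd']``.
    """
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    ref = ct.loc[reference_gene]
    if ref.isna().any():
        raise ValueError("reference gene Ct missing in some segment")
    dct = ct.drop(index=reference_gene).sub(ref, axis=1)
    if transform == "power2":
        rel = np.power(2.0, -dct)
    elif transform == "linear":
        rel = -dct
    else:
        raise ValueError(f"unknown transform {transform!r}")

    missing = rel.isna().any(axis=1)
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=1)
    zero_sd = (sd == 0) & ~missing
    safe_sd = sd.where(sd > 0, 1.0)
    z = rel.sub(mean, axis=0).div(safe_sd, axis=0)
    z[zero_sd] = 0.0
    z[missing] = np.nan
    z.attrs["zero_sd"] = z.index[zero_sd].tolist()
    z.attrs["missing"] = z.index[missing].tolist()
    return z


def line_composition(
    assignments,
    cell_types,
    confident_labels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type (plus overall) fractions of donor-line assignments.

    With ``confident_labels`` set, fractions are renormalized over those two
    labels only (cells with other assignments are dropped from the
    denominator), matching the "confidently assigned" convention.
    """
    a = pd.Series(np.asarray(assignments), name="assignment")
    t = pd.Series(np.asarray(cell_types), name="cell_type")
    if len(a) != len(t):
        raise ValueError("assignments and cell_types differ in length")
    df = pd.DataFrame({"assignment": a.to_numpy(), "cell_type": t.to_numpy()})
    if confident_labels is not None:
        df = df[df["assignment"].isin(confident_labels)]
    counts = pd.crosstab(df["cell_type"], df["assignment"])
    counts.loc["overall"] = counts.sum(axis=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.columns.name = None
    frac.index.name = "cell_type"
    return frac
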