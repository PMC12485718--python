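"""Reading and writing the package's on-disk formats.

Counts travel as a 10x-style directory (Matrix-Market ``matrix.mtx`` stored
gene x cell, ``genes.tsv`` with gene_id/symbol/chromosome/biotype,
``barcodes.tsv``); everything else is plain TSV/CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "write_counts_dir",
    "read_counts_dir",
    "write_ground_truth",
    "write_embedding_csv",
    "read_embedding_csv",
    "write_json",
]


def write_counts_dir(adata: AnnData, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    genes = adata.var.copy()
    if "gene_id" not in genes.columns:
        genes.insert(0, "gene_id", adata.var_names)
    keep = [c for c in ("gene_id", "symbol", "chromosome", "biotype") if c in genes]
    genes[keep].to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")
    return outdir


def read_counts_dir(indir: str | Path) -> AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
    var = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
    var["gene_id"] = var.index
    if "chromosome" in var:
        var["mt"] = var["chromosome"].astype(str) == "MT"
    if "symbol" in var:
        var["ribo"] = var["symbol"].astype(str).str.match(r"^RP[SL]")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes.astype(str), name="cell_id"))
    meta = indir / "cell_metadata.tsv"
    if meta.exists():
        obs = pd.read_csv(meta, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return AnnData(X=X, obs=obs, var=var)


def write_ground_truth(truth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(outdir / "ground_truth_cells.tsv", sep="\t")
    with open(outdir / "correspondence.json", "w") as fh:
        json.dump(truth.correspondence, fh, indent=1)
    with open(outdir / "marker_genes.json", "w") as fh:
        json.dump(truth.marker_genes, fh, indent=1)


def write_embedding_csv(embedding, path: str | Path) -> None:
    embedding.coordinates.to_csv(path)


def read_embedding_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
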