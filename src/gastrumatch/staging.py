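"""In-silico developmental staging by k-nearest neighbors in PC space.

Query cells are placed in a joint PC embedding with a staged reference
atlas; the stage (or cell-type) labels of each query cell's nearest
reference neighbors give a per-cell composition, which is aggregated per
cell type to infer the stage a dataset most resembles. Two neighbor modes
are provided: ``per_stage_pool`` finds the k nearest reference cells within
each stage separately, pools the candidates and keeps the k globally
nearest (the staging convention, k=15); ``global`` is a plain kNN over all
reference cells (the cell-type composition convention, k=20). Distances are
Euclidean; ties break deterministically by reference cell order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .preprocess import Embedding, HVGSelector, PCAEmbedder, ScaleRegressor, _as_dense

__all__ = [
    "KNNStager",
    "joint_embed",
    "knn_reference_composition",
    "aggregate_composition",
]


def joint_embed(datasets: list[AnnData], d: int = 30, n_hvg: int = 2500) -> Embedding:
    """Joint PCA of several log-normalized datasets on shared HVGs.

    Concatenates cells over the shared gene universe, selects HVGs on the
    concatenated matrix, scales and runs PCA to ``d`` dimensions. Per-cell
    dataset/stage/type labels are carried through.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    shared = datasets[0].var_names
    for ad in datasets[1:]:
        shared = shared.intersection(ad.var_names)
    if len(shared) == 0:
        raise ValueError("empty shared gene universe")

    mats = [_as_dense(ad[:, shared].X) for ad in datasets]
    X = np.concatenate(mats, axis=0)
    labels = []
    for i, ad in enumerate(datasets):
        lab = pd.DataFrame(index=ad.obs_names)
        lab["dataset"] = ad.obs.get("dataset", pd.Series(f"D{i}", index=ad.obs_names))
        for col in ("stage", "cell_type"):
            if col in ad.obs:
                lab[col] = ad.obs[col].to_numpy()
        labels.append(lab)
    labels = pd.concat(labels)
    index = labels.index

    hvg = HVGSelector(n_top=min(n_hvg, X.shape[1])).fit(X)
    Xh = hvg.transform(X)
    Xs = ScaleRegressor().fit_transform(Xh)
    emb = PCAEmbedder(n_comps=d).fit(Xs)
    coords = emb.transform(Xs)
    cols = [f"PC{i + 1}" for i in range(d)]
    return Embedding(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        explained_variance=emb.explained_variance_,
        explained_variance_ratio=emb.explained_variance_ratio_,
        loadings=pd.DataFrame(
            emb.components_.T, index=shared[hvg.highly_variable_], columns=cols
        ),
        labels=labels,
    )


def _topk_by_distance(
    dist: np.ndarray, ref_pos: np.ndarray, k: int
) -> np.ndarray:
    """Indices (into ref_pos) of the k nearest, ties by reference order."""
    order = np.lexsort((ref_pos, dist))
    return order[:k]


@dataclass
class _Reference:
    coords: np.ndarray
    stage: np.ndarray
    cell_type: np.ndarray | None


class KNNStager(BaseEstimator):
    """kNN label-composition estimator against a staged reference.

    ``fit`` stores the reference coordinates and labels; ``composition``
    returns, for each query cell, the fraction of each reference label among
    its k nearest reference neighbors under the configured mode.
    """

    def __init__(self, k: int = 15, mode: str = "per_stage_pool",
                 chunk_size: int = 512):
        self.k = k
        self.mode = mode
        self.chunk_size = chunk_size

    def fit(self, coordinates, stage=None, cell_type=None):
        coords = np.asarray(coordinates, dtype=float)
        if self.mode not in ("per_stage_pool", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "per_stage_pool" and stage is None:
            raise ValueError("per_stage_pool mode requires reference stages")
        self.reference_ = _Reference(
            coords=coords,
            stage=None if stage is None else np.asarray(stage),
            cell_type=None if cell_type is None else np.asarray(cell_type),
        )
        if self.mode == "per_stage_pool":
            counts = pd.Series(self.reference_.stage).value_counts()
            if self.k > counts.min():
                raise ValueError("k exceeds the smallest per-stage reference size")
        elif self.k > coords.shape[0]:
            raise ValueError("k exceeds the reference size")
        return self

    def _labels(self, label_kind: str) -> np.ndarray:
        ref = self.reference_
        if label_kind == "stage":
            if ref.stage is None:
                raise ValueError("reference has no stage labels")
            return ref.stage
        if label_kind == "cell_type":
            if ref.cell_type is None:
                raise ValueError("reference has no cell_type labels")
            return ref.cell_type
        raise ValueError(f"unknown label_kind {label_kind!r}")

    def composition(self, query, label_kind: str = "stage") -> pd.DataFrame:
        """Query x label DataFrame of neighbor-label fractions (rows sum to 1)."""
        Q = np.asarray(
            query.coordinates if isinstance(query, Embedding) else query,
            dtype=float,
        )
        ref = self.reference_
        if Q.shape[1] != ref.coords.shape[1]:
            raise ValueError("query/reference dimensionality mismatch")
        labels = self._labels(label_kind)
        label_values = pd.unique(labels)
        label_values = np.array(sorted(label_values, key=str))
        label_pos = {v: i for i, v in enumerate(label_values)}

        out = np.zeros((Q.shape[0], len(label_values)))
        ref_pos_all = np.arange(ref.coords.shape[0])

        if self.mode == "per_stage_pool":
            stages = np.array(sorted(pd.unique(ref.stage), key=str))
            stage_idx = [np.flatnonzero(ref.stage == s) for s in stages]
        for start in range(0, Q.shape[0], self.chunk_size):
            chunk = Q[start:start + self.chunk_size]
            if self.mode == "global":
                D = cdist(chunk, ref.coords)
                for qi in range(chunk.shape[0]):
                    sel = _topk_by_distance(D[qi], ref_pos_all, self.k)
                    for lab in labels[sel]:
                        out[start + qi, label_pos[lab]] += 1
            else:
                Ds = [cdist(chunk, ref.coords[idx]) for idx in stage_idx]
                for qi in range(chunk.shape[0]):
                    cand_pos = []
                    cand_dist = []
                    for D, idx in zip(Ds, stage_idx):
                        sel = _topk_by_distance(D[qi], idx, self.k)
                        cand_pos.append(idx[sel])
                        cand_dist.append(D[qi][sel])
                    cand_pos = np.concatenate(cand_pos)
                    cand_dist = np.concatenate(cand_dist)
                    sel = _topk_by_distance(cand_dist, cand_pos, self.k)
                    for lab in labels[cand_pos[sel]]:
                        out[start + qi, label_pos[lab]] += 1
        out /= self.k
        idx = (
            query.coordinates.index
            if isinstance(query, Embedding)
            else pd.RangeIndex(Q.shape[0])
        )
        return pd.DataFrame(out, index=idx, columns=label_values)


def knn_reference_composition(
    query,
    reference_coords,
    k: int = 15,
    label_kind: str = "stage",
    mode: str = "per_stage_pool",
    stage=None,
    cell_type=None,
) -> pd.DataFrame:
    stager = KNNStager(k=k, mode=mode).fit(
        reference_coords, stage=stage, cell_type=cell_type
    )
    return stager.composition(query, label_kind=label_kind)


def aggregate_composition(
    compositions: pd.DataFrame, groups, top_m: int = 5
) -> pd.DataFrame:
    """Per-group mean label fractions, modal label and top-m labels.

    Group fractions are the renormalized mean of member cells' fraction
    vectors; the modal label is the argmax with ties broken by label order.
    Empty groups are excluded with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=compositions.index)
    if groups.isna().any():
        warnings.warn("queries with missing group labels are excluded")
        keep = ~groups.isna()
        compositions, groups = compositions[keep], groups[keep]
    mean = compositions.groupby(groups).mean()
    mean = mean.div(mean.sum(axis=1), axis=0)
    # idxmax already breaks ties by column (label) order
    summary = mean.copy()
    summary["modal_label"] = mean.idxmax(axis=1)
    summary["top_labels"] = [
        ";".join(
            row.sort_values(ascending=False, kind="stable").index[:top_m].astype(str)
        )
        for _, row in mean.iterrows()
    ]
    return summary
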