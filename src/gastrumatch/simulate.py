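"""Synthetic paired scRNA-seq datasets with planted ground truth.

Emulates the statistical structure the downstream analyses assume: discrete
cell types driven by marker genes, an ordinal developmental-stage gradient
along a fixed gene direction, lognormal library sizes, negative-binomial
(Gamma-Poisson) counts with a shared dispersion, mitochondrial / ribosomal /
sex-chromosome gene annotation, and doublets formed by summing two singlet
cells' count vectors. Every planted quantity (type, stage, doublet status,
cross-dataset type correspondence, marker genes) is recorded so recovery can
be scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "SimSpec",
    "GroundTruth",
    "generate_dataset",
    "generate_paired_datasets",
    "generate_qc_fixture",
]


@dataclass
class SimSpec:
    """Parameters of the count simulator.

    Log-scale effect sizes act on the softmax logits of per-gene expression
    proportions; ``type_effect`` is the marker log-fold size, ``stage_effect``
    the log-mean shift per stage step along a fixed random gene direction.
    ``nb_dispersion`` is the Gamma shape (NB size) parameter: variance =
    mu + mu^2 / nb_dispersion.
    """

    n_genes: int = 2000
    frac_mt: float = 0.01
    frac_ribo: float = 0.05
    frac_coding: float = 0.80
    n_types: int = 10
    cells_per_type: int = 200
    n_stages: int = 1
    stage_effect: float = 0.0
    type_effect: float = 2.0
    n_markers_per_type: int = 50
    batch_effect: float = 0.3
    nb_dispersion: float = 2.0
    libsize_logmean: float = math.log(20_000.0)
    libsize_logsd: float = 0.35
    doublet_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_mt", "frac_ribo", "frac_coding", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.doublet_rate >= 0.5:
            raise ValueError("doublet_rate must be < 0.5")
        for name in ("n_genes", "n_types", "cells_per_type", "n_stages",
                     "n_markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.type_effect < 0 or self.stage_effect < 0 or self.batch_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError("n_markers_per_type * n_types exceeds n_genes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset (or dataset pair)."""

    cells: pd.DataFrame
    correspondence: dict = field(default_factory=dict)
    marker_genes: dict = field(default_factory=dict)


def _make_gene_table(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Gene annotation with exact-count chromosome/biotype proportions."""
    n = spec.n_genes
    n_mt = round(spec.frac_mt * n)
    n_ribo = round(spec.frac_ribo * n)
    n_rest = n - n_mt - n_ribo
    if n_rest < 0:
        raise ValueError("frac_mt + frac_ribo exceed 1")

    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    chrom = np.empty(n, dtype=object)
    ribo = np.zeros(n, dtype=bool)
    symbols = gene_ids.copy()

    # MT genes first, then ribosomal (autosomal), then the rest.
    chrom[:n_mt] = "MT"
    symbols[:n_mt] = [f"MT-G{i}" for i in range(n_mt)]
    ribo[n_mt:n_mt + n_ribo] = True
    symbols[n_mt:n_mt + n_ribo] = [
        (f"RPS{i}" if i % 2 == 0 else f"RPL{i}") for i in range(n_ribo)
    ]
    autosomes = [str(c) for c in range(1, 23)]
    chrom[n_mt:n_mt + n_ribo] = rng.choice(autosomes, size=n_ribo)

    # ~5% X and ~2% Y among the remaining genes, rest autosomal.
    n_x = round(0.05 * n_rest)
    n_y = round(0.02 * n_rest)
    rest_chrom = np.array(
        ["X"] * n_x + ["Y"] * n_y
        + list(rng.choice(autosomes, size=n_rest - n_x - n_y))
    )
    rng.shuffle(rest_chrom)
    chrom[n_mt + n_ribo:] = rest_chrom

    # Biotypes: exact counts; MT and ribosomal genes are protein_coding.
    n_coding = round(spec.frac_coding * n)
    n_linc = round(0.5 * (n - n_coding))
    biotype = np.array(
        ["protein_coding"] * n_coding + ["lincRNA"] * n_linc
        + ["other"] * (n - n_coding - n_linc), dtype=object
    )
    # keep protein_coding on MT/ribo rows: shuffle only the tail block
    tail = biotype[n_mt + n_ribo:].copy()
    rng.shuffle(tail)
    biotype[n_mt + n_ribo:] = tail

    var = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "chromosome": chrom,
            "biotype": biotype,
            "mt": chrom == "MT",
            "ribo": ribo,
        },
        index=gene_ids,
    )
    var.index.name = "gene_id"
    return var


def _marker_pool(var: pd.DataFrame) -> np.ndarray:
    """Indices of genes eligible as cell-type markers (autosomal, not MT/ribo)."""
    ok = (~var["mt"].to_numpy()) & (~var["ribo"].to_numpy()) & (
        ~np.isin(var["chromosome"].to_numpy(), ["X", "Y"])
    )
    return np.flatnonzero(ok)


def _assign_markers(
    spec: SimSpec, var: pd.DataFrame, rng: np.random.Generator, n_sets: int
) -> list[np.ndarray]:
    pool = _marker_pool(var)
    need = spec.n_markers_per_type * n_sets
    if need > pool.size:
        raise ValueError("not enough eligible genes for the requested markers")
    chosen = rng.choice(pool, size=need, replace=False)
    return [
        np.sort(chosen[i * spec.n_markers_per_type:(i + 1) * spec.n_markers_per_type])
        for i in range(n_sets)
    ]


def _nb_draw(rng: np.random.Generator, lam: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with mean lam, shape theta."""
    shape = rng.gamma(theta, lam / theta)
    return rng.poisson(shape)


def _sample_block(
    spec: SimSpec,
    rng: np.random.Generator,
    base: np.ndarray,
    gradient: np.ndarray,
    batch_shift: np.ndarray,
    markers: dict[str, np.ndarray],
    type_labels: list[str],
    n_stages: int,
    prefix: str,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Draw singlet cells for every (type, stage) combination."""
    n_genes = spec.n_genes
    rows: list[np.ndarray] = []
    obs_type: list[str] = []
    obs_stage: list[int] = []

    for t in type_labels:
        logits = base + spec.batch_effect * batch_shift
        m = markers[t]
        stage_of_cell = np.tile(np.arange(n_stages), spec.cells_per_type)[
            : spec.cells_per_type
        ]
        libsize = rng.lognormal(spec.libsize_logmean, spec.libsize_logsd,
                                size=spec.cells_per_type)
        for s in range(n_stages):
            idx = np.flatnonzero(stage_of_cell == s)
            if idx.size == 0:
                continue
            lg = logits.copy()
            lg[m] += spec.type_effect
            lg = lg + spec.stage_effect * s * gradient
            lg -= lg.max()
            p = np.exp(lg)
            p /= p.sum()
            lam = libsize[idx, None] * p[None, :]
            counts = _nb_draw(rng, lam, spec.nb_dispersion)
            rows.append(counts)
            obs_type.extend([t] * idx.size)
            obs_stage.extend([s] * idx.size)

    X = np.concatenate(rows, axis=0)
    n_cells = X.shape[0]
    obs = pd.DataFrame(
        {
            "cell_type": obs_type,
            "stage": obs_stage,
            "is_doublet": False,
        },
        index=[f"{prefix}{i:06d}" for i in range(n_cells)],
    )
    obs.index.name = "cell_id"
    return sp.csr_matrix(X), obs


def _add_doublets(
    spec: SimSpec,
    rng: np.random.Generator,
    X: sp.csr_matrix,
    obs: pd.DataFrame,
    prefix: str,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Append doublets as sums of two singlet cells of distinct types."""
    n_singlet = X.shape[0]
    n_doub = round(spec.doublet_rate * n_singlet)
    obs = obs.copy()
    obs["doublet_score"] = np.clip(
        rng.normal(0.05, 0.05, size=n_singlet), 0.0, 1.0
    )
    obs["parent_a"] = ""
    obs["parent_b"] = ""
    if n_doub == 0:
        return X, obs

    types = obs["cell_type"].to_numpy()
    pairs = []
    while len(pairs) < n_doub:
        a, b = rng.integers(0, n_singlet, size=2)
        if types[a] != types[b]:
            pairs.append((a, b))
    a_idx = np.array([p[0] for p in pairs])
    b_idx = np.array([p[1] for p in pairs])
    Xd = X[a_idx] + X[b_idx]
    ids = obs.index.to_numpy()
    dobs = pd.DataFrame(
        {
            "cell_type": types[a_idx],
            "stage": obs["stage"].to_numpy()[a_idx],
            "is_doublet": True,
            "doublet_score": np.clip(
                rng.normal(0.5, 0.05, size=n_doub), 0.0, 1.0
            ),
            "parent_a": ids[a_idx],
            "parent_b": ids[b_idx],
        },
        index=[f"{prefix}dbl{i:05d}" for i in range(n_doub)],
    )
    dobs.index.name = "cell_id"
    return sp.vstack([X, sp.csr_matrix(Xd)]).tocsr(), pd.concat([obs, dobs])


def generate_dataset(spec: SimSpec) -> tuple[AnnData, GroundTruth]:
    """Simulate one dataset; counts in ``X`` (cells x genes), truth in obs.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    var = _make_gene_table(spec, rng)
    base = rng.normal(0.0, 1.0, size=spec.n_genes)
    gradient = rng.normal(0.0, 1.0, size=spec.n_genes)
    gradient /= gradient.std()
    batch_shift = rng.normal(0.0, 1.0, size=spec.n_genes)

    type_labels = [f"T{i:02d}" for i in range(spec.n_types)]
    marker_sets = _assign_markers(spec, var, rng, spec.n_types)
    markers = dict(zip(type_labels, marker_sets))

    X, obs = _sample_block(
        spec, rng, base, gradient, batch_shift, markers, type_labels,
        spec.n_stages, prefix="c",
    )
    X, obs = _add_doublets(spec, rng, X, obs, prefix="c")
    adata = AnnData(X=X, obs=obs, var=var.copy())
    adata.uns["sim_spec"] = spec.to_dict()
    truth = GroundTruth(
        cells=obs.copy(),
        correspondence={},
        marker_genes={t: var.index.to_numpy()[m].tolist()
                      for t, m in markers.items()},
    )
    return adata, truth


def generate_paired_datasets(
    spec: SimSpec, shared_types: int
) -> tuple[AnnData, AnnData, GroundTruth]:
    """Two datasets sharing ``shared_types`` type-level mean profiles.

    Both datasets have ``spec.n_types`` clusters; the first ``shared_types``
    of B reuse A's base/marker structure (the planted correspondence), the
    remainder get independent markers. Each dataset receives an independent
    batch shift of size ``spec.batch_effect``; only dataset B carries a stage
    gradient (dataset A is a single snapshot, stage 0).
    """
    spec.validate()
    if not 0 <= shared_types <= spec.n_types:
        raise ValueError("shared_types must be in [0, n_types]")

    rng = np.random.default_rng(spec.seed)
    var = _make_gene_table(spec, rng)
    base = rng.normal(0.0, 1.0, size=spec.n_genes)
    gradient = rng.normal(0.0, 1.0, size=spec.n_genes)
    gradient /= gradient.std()

    n_unshared = spec.n_types - shared_types
    sets = _assign_markers(spec, var, rng, spec.n_types + n_unshared)
    a_labels = [f"A{i:02d}" for i in range(spec.n_types)]
    b_labels = [f"B{i:02d}" for i in range(spec.n_types)]
    a_markers = dict(zip(a_labels, sets[: spec.n_types]))
    b_markers = {}
    for i, lab in enumerate(b_labels):
        if i < shared_types:
            b_markers[lab] = a_markers[a_labels[i]]
        else:
            b_markers[lab] = sets[spec.n_types + (i - shared_types)]

    rng_a = np.random.default_rng(spec.seed + 1)
    rng_b = np.random.default_rng(spec.seed + 2)
    shift_a = rng_a.normal(0.0, 1.0, size=spec.n_genes)
    shift_b = rng_b.normal(0.0, 1.0, size=spec.n_genes)

    Xa, obs_a = _sample_block(spec, rng_a, base, gradient, shift_a,
                              a_markers, a_labels, 1, prefix="a")
    Xa, obs_a = _add_doublets(spec, rng_a, Xa, obs_a, prefix="a")
    Xb, obs_b = _sample_block(spec, rng_b, base, gradient, shift_b,
                              b_markers, b_labels, spec.n_stages, prefix="b")
    Xb, obs_b = _add_doublets(spec, rng_b, Xb, obs_b, prefix="b")

    ad_a = AnnData(X=Xa, obs=obs_a, var=var.copy())
    ad_b = AnnData(X=Xb, obs=obs_b, var=var.copy())
    obs_a2 = obs_a.copy()
    obs_a2["dataset"] = "A"
    obs_b2 = obs_b.copy()
    obs_b2["dataset"] = "B"
    gene_ids = var.index.to_numpy()
    truth = GroundTruth(
        cells=pd.concat([obs_a2, obs_b2]),
        correspondence={a_labels[i]: b_labels[i] for i in range(shared_types)},
        marker_genes={
            **{t: gene_ids[m].tolist() for t, m in a_markers.items()},
            **{t: gene_ids[m].tolist() for t, m in b_markers.items()},
        },
    )
    return ad_a, ad_b, truth


# ---------------------------------------------------------------------------
# QC boundary fixture
# ---------------------------------------------------------------------------

_FIXTURE_DEFAULT = dict(umi=10_000, genes=1_200, mt_frac=0.02,
                        ribo_frac=0.10, score=0.05)

# (name, overrides) for every filtering boundary; strict inequalities mean
# the boundary value itself is retained.
_BOUNDARY_CELLS = [
    ("umi_999", dict(umi=999, genes=600)),
    ("umi_1000", dict(umi=1000, genes=600)),
    ("umi_4999", dict(umi=4999, genes=900)),
    ("umi_5000", dict(umi=5000, genes=900)),
    ("genes_499", dict(genes=499)),
    ("genes_500", dict(genes=500)),
    ("mt_9p9", dict(mt_frac=0.099)),
    ("mt_10p1", dict(mt_frac=0.101)),
    ("ribo_39", dict(ribo_frac=0.39)),
    ("ribo_41", dict(ribo_frac=0.41)),
    ("score_0p19", dict(score=0.19)),
    ("score_0p20", dict(score=0.20)),
    ("score_0p21", dict(score=0.21)),
]


def _fixture_cell_counts(
    umi: int, genes: int, mt_frac: float, ribo_frac: float,
    var: pd.DataFrame, rng: np.random.Generator,
) -> np.ndarray:
    """One count vector with exact UMI total, detected-gene count and
    MT/ribo UMI fractions."""
    n = len(var)
    mt_idx = np.flatnonzero(var["mt"].to_numpy())
    ribo_idx = np.flatnonzero(var["ribo"].to_numpy())
    other_idx = np.flatnonzero(~(var["mt"].to_numpy() | var["ribo"].to_numpy()))

    mt_umi = round(mt_frac * umi)
    ribo_umi = round(ribo_frac * umi)
    counts = np.zeros(n, dtype=np.int64)

    def spread(idx_pool, total, n_slots):
        if total == 0:
            return 0
        n_slots = max(1, min(n_slots, total, idx_pool.size))
        chosen = idx_pool[:n_slots]
        counts[chosen] += 1
        counts[chosen[0]] += total - n_slots
        return n_slots

    used = spread(mt_idx, mt_umi, 3)
    used += spread(ribo_idx, ribo_umi, 5)
    n_other = genes - used
    other_umi = umi - mt_umi - ribo_umi
    if n_other < 1 or other_umi < n_other or n_other > other_idx.size:
        raise ValueError("infeasible fixture cell parameters")
    chosen = rng.choice(other_idx, size=n_other, replace=False)
    counts[chosen] += 1
    counts[chosen[0]] += other_umi - n_other
    return counts


def generate_qc_fixture(n_cells: int = 1000, seed: int = 0) -> AnnData:
    """Cells straddling every cell-filter boundary, with intended outcomes.

    The returned AnnData's obs records the construction targets
    (``umi_total_recorded`` etc.), the per-rule intended pass flags and the
    overall ``expect_retained`` flag under the default two-pass filter rules,
    including exactly ceil(0.001 * N_pass1) planted extreme-UMI cells that
    the top-0.1% rule should remove.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)
    spec = SimSpec(n_genes=2000, frac_mt=0.005, frac_ribo=0.025, seed=seed)
    var = _make_gene_table(spec, rng)

    cells: list[dict] = []
    for name, over in _BOUNDARY_CELLS:
        params = dict(_FIXTURE_DEFAULT)
        params.update(over)
        cells.append({"name": name, **params})

    # Pass-1 failures are fixed by construction; the extreme-UMI count
    # depends on the pass-1 survivor count, which we therefore compute first.
    n_background = n_cells - len(cells)
    if n_background < 1:
        raise ValueError("n_cells too small for the boundary set")
    n_fail_pass1 = sum(
        1 for c in cells if c["umi"] < 1000 or c["genes"] < 500
    )
    n_pass1 = n_cells - n_fail_pass1
    n_top = math.ceil(0.001 * n_pass1)

    for i in range(n_top):
        cells.append({"name": f"top_umi_{i}", "umi": 500_000 + 1000 * i,
                      "genes": 1500, "mt_frac": 0.02, "ribo_frac": 0.10,
                      "score": 0.05})
    for i in range(n_background - n_top):
        cells.append({
            "name": f"bg_{i:04d}",
            "umi": int(rng.integers(6000, 20000)),
            "genes": int(rng.integers(800, 1500)),
            "mt_frac": float(rng.uniform(0.005, 0.08)),
            "ribo_frac": float(rng.uniform(0.05, 0.30)),
            "score": float(rng.uniform(0.0, 0.15)),
        })

    mat = np.zeros((len(cells), len(var)), dtype=np.int64)
    rows = []
    for i, c in enumerate(cells):
        counts = _fixture_cell_counts(
            c["umi"], c["genes"], c["mt_frac"], c["ribo_frac"], var, rng
        )
        mat[i] = counts
        umi = int(counts.sum())
        mt_pct = 100.0 * counts[var["mt"].to_numpy()].sum() / umi
        ribo_pct = 100.0 * counts[var["ribo"].to_numpy()].sum() / umi
        genes_det = int((counts > 0).sum())
        rows.append({
            "cell_id": c["name"],
            "umi_total_recorded": umi,
            "genes_detected_recorded": genes_det,
            "mt_pct_recorded": mt_pct,
            "ribo_pct_recorded": ribo_pct,
            "doublet_score": c["score"],
            "pass_umi_min_1000": umi >= 1000,
            "pass_genes_min_500": genes_det >= 500,
            "pass_umi_min_5000": umi >= 5000,
            "pass_doublet_max": c["score"] <= 0.2,
            "pass_mt_max": mt_pct <= 10.0,
            "pass_ribo_max": ribo_pct <= 40.0,
            "pass_umi_top_frac": not c["name"].startswith("top_umi_"),
        })
    obs = pd.DataFrame(rows).set_index("cell_id")
    pass_cols = [c for c in obs.columns if c.startswith("pass_")]
    obs["expect_retained"] = obs[pass_cols].all(axis=1)
    adata = AnnData(X=sp.csr_matrix(mat), obs=obs, var=var)
    adata.uns["n_top_frac_expected"] = int(n_top)
    return adata
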