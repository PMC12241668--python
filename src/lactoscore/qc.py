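"""Quality control, normalization, HVG selection, PCA and clustering.

Filtering follows the standard droplet-scRNA-seq protocol: genes detected in
fewer than 5 cells are dropped, cells must show 200-7,000 detected genes
(inclusive bounds) and at most 20% mitochondrial counts (cells strictly above
the threshold are removed). The gene filter runs first; cell filters are
evaluated on the gene-filtered matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "HvgPcaParams",
    "QCReport",
    "apply_qc",
    "lognormalize",
    "select_hvgs",
    "run_pca",
    "cluster_cells",
    "find_markers",
]


@dataclass
class QCThresholds:
    min_cells_per_gene: int = 5
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 7000
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell > max_genes_per_cell")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0,1]")


@dataclass
class HvgPcaParams:
    n_hvgs: int = 2000
    n_pcs: int = 20

    def __post_init__(self) -> None:
        if self.n_hvgs <= 0 or self.n_pcs <= 0:
            raise ValueError("n_hvgs and n_pcs must be positive")
        if self.n_hvgs < self.n_pcs:
            raise ValueError("n_hvgs must be >= n_pcs")


@dataclass
class QCReport:
    n_genes_in: int = 0
    n_cells_in: int = 0
    genes_removed_min_cells: int = 0
    cells_removed_low_genes: int = 0
    cells_removed_high_genes: int = 0
    cells_removed_mito: int = 0
    n_genes_out: int = 0
    n_cells_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def apply_qc(
    cm: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Filter genes then cells by detection counts and mitochondrial load.

    Each round applies the gene filter first, then the cell filters on the
    gene-filtered matrix; rounds repeat until nothing changes (cell removal
    can push genes back below the prevalence threshold), so the operation is
    idempotent. The report accumulates per-rule removal counts over rounds.
    """
    if cm.layer_tag != "counts":
        raise ValueError("apply_qc expects the counts layer")
    th = thresholds or QCThresholds()
    report = QCReport(n_genes_in=cm.n_genes, n_cells_in=cm.n_cells)

    while True:
        detected = cm.values > 0
        cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
        gene_keep = cells_per_gene >= th.min_cells_per_gene
        report.genes_removed_min_cells += int((~gene_keep).sum())
        cm = cm.subset_genes(gene_keep)

        detected = cm.values > 0
        genes_per_cell = np.asarray(detected.sum(axis=1)).ravel()
        low = genes_per_cell < th.min_genes_per_cell
        high = genes_per_cell > th.max_genes_per_cell

        mito_cols = np.array(
            [g.startswith(th.mito_prefix) for g in cm.gene_ids], dtype=bool
        )
        total = np.asarray(cm.values.sum(axis=1)).ravel().astype(float)
        mito = np.asarray(cm.values[:, mito_cols].sum(axis=1)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / total, 0.0)
        mito_bad = mito_frac > th.max_mito_fraction  # strictly above is removed

        report.cells_removed_low_genes += int(low.sum())
        report.cells_removed_high_genes += int(high.sum())
        report.cells_removed_mito += int((mito_bad & ~low & ~high).sum())
        cell_keep = ~(low | high | mito_bad)
        if not cell_keep.any():
            raise ValueError(
                "all cells removed by QC "
                f"(low-genes={report.cells_removed_low_genes}, "
                f"high-genes={report.cells_removed_high_genes}, "
                f"mito={report.cells_removed_mito})"
            )
        changed = (not gene_keep.all()) or (not cell_keep.all())
        cm = cm.subset_cells(cell_keep)
        if not changed:
            break
    report.n_genes_out, report.n_cells_out = cm.n_genes, cm.n_cells
    return cm, report


def lognormalize(cm: CountMatrix, scale_total: float = 1e4) -> CountMatrix:
    """Per-cell total-count scaling to ``scale_total`` followed by ln(1+x)."""
    if cm.layer_tag != "counts":
        raise ValueError("lognormalize expects the counts layer")
    values = sp.csr_matrix(cm.values, dtype=float)
    totals = np.asarray(values.sum(axis=1)).ravel()
    scale = np.where(totals > 0, scale_total / np.where(totals > 0, totals, 1.0), 0.0)
    values = sp.diags(scale) @ values
    values.data = np.log1p(values.data)
    return CountMatrix(
        values=values, cell_ids=cm.cell_ids, gene_ids=cm.gene_ids,
        layer_tag="lognorm",
    )


def select_hvgs(cm: CountMatrix, n_hvgs: int = 2000, n_bins: int = 20) -> list[str]:
    """Top genes by binned standardized dispersion (classic Seurat-v1 style).

    Dispersion = variance/mean per gene on the de-logged (expm1) scale,
    z-scored within ``n_bins`` equal-count bins of mean expression — the
    log scale compresses high-expression variance and would bury genuinely
    variable genes. Ties break lexicographically by gene id so the
    selection is fully deterministic.
    """
    if cm.layer_tag != "lognorm":
        raise ValueError("select_hvgs expects log-normalized values")
    if n_hvgs > cm.n_genes:
        warnings.warn(
            f"n_hvgs={n_hvgs} exceeds gene count {cm.n_genes}; returning all genes"
        )
        n_hvgs = cm.n_genes
    x = np.expm1(cm.dense())
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)

    order = np.argsort(mean, kind="stable")
    bins = np.empty(cm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(cm.n_genes) * n_bins) // cm.n_genes, n_bins - 1
    )
    z = np.zeros(cm.n_genes)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        d = dispersion[in_bin]
        sd = d.std()
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0

    # sort by descending z, ties by gene id
    keys = sorted(range(cm.n_genes), key=lambda i: (-z[i], cm.gene_ids[i]))
    return [cm.gene_ids[i] for i in keys[:n_hvgs]]


def run_pca(
    cm: CountMatrix, genes: list[str] | None = None, n_pcs: int = 20
) -> pd.DataFrame:
    """PCA on centered, unit-scaled genes with a deterministic sign convention.

    Each loading vector's largest-magnitude entry is made positive, so the
    embedding is reproducible across BLAS backends.
    """
    sub = cm if genes is None else cm.subset_genes(
        np.isin(cm.gene_ids.astype(str), list(genes))
    )
    x = sub.dense()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    n_pcs = min(n_pcs, min(x.shape) - 1) if min(x.shape) > 1 else 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # sign fix: largest-|.| loading entry positive per component
    for j in range(n_pcs):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    emb = u * s
    return pd.DataFrame(
        emb, index=sub.cell_ids, columns=[f"PC{j + 1}" for j in range(n_pcs)]
    )


def cluster_cells(
    embedding: pd.DataFrame,
    resolution: float = 0.8,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Leiden community detection on a kNN graph of the embedding.

    Returns consecutive integer labels ordered by descending cluster size.
    The graph construction and community detection are delegated to
    scikit-learn / igraph / leidenalg.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    n = len(embedding)
    if n <= n_neighbors:
        raise ValueError(
            f"{n} cells but {n_neighbors} neighbors requested; too few cells"
        )
    knn = kneighbors_graph(embedding.to_numpy(), n_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(knn.row.tolist(), knn.col.tolist())), directed=False
    )
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by descending size, stable in original label for ties
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return pd.Series([remap[l] for l in labels], index=embedding.index, name="cluster")


def _seurat_log2fc(x_group: np.ndarray, x_rest: np.ndarray) -> float:
    """log2((mean(expm1)+1) / (mean(expm1)+1)) on log-normalized values."""
    return float(
        np.log2((np.expm1(x_group).mean() + 1.0) / (np.expm1(x_rest).mean() + 1.0))
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when both groups are small and
    tie-free, else tie-corrected normal approximation."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def find_markers(
    cm: CountMatrix,
    groups: pd.Series,
    p_max: float = 0.01,
    lfc_min: float = 0.25,
) -> pd.DataFrame:
    """Positive cluster markers: Wilcoxon group-vs-rest on lognorm values.

    Reports genes with p < ``p_max`` and log2 fold change > ``lfc_min``
    (up-regulated in the group only), per group.
    """
    if cm.layer_tag != "lognorm":
        raise ValueError("find_markers expects log-normalized values")
    groups = groups.reindex(cm.cell_ids)
    x = cm.dense()
    rows = []
    for grp in sorted(pd.unique(groups.dropna())):
        in_grp = (groups == grp).to_numpy()
        a, b = x[in_grp], x[~in_grp]
        if not in_grp.any() or in_grp.all():
            continue
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
        for j, gene in enumerate(cm.gene_ids):
            lfc = _seurat_log2fc(a[:, j], b[:, j])
            p = float(res.pvalue[j])
            if p < p_max and lfc > lfc_min:
                rows.append(
                    {"group": grp, "gene": gene, "log2fc": lfc, "p": p}
                )
    return pd.DataFrame(rows, columns=["group", "gene", "log2fc", "p"])
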