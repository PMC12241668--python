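"""Weighted co-expression network core: metacells, soft threshold, TOM,
module detection, eigengenes and kME hub genes.

The pipeline mirrors the single-cell flavor of WGCNA: counts are first
aggregated into metacells (sums over k nearest neighbors in the PCA
embedding) to de-sparsify correlation estimates, then a signed-magnitude
adjacency a_ij = |cor|^beta is raised to a soft power chosen for scale-free
topology, turned into a topological overlap matrix, clustered by average
linkage and cut at a fixed height. Modules get WGCNA-style color labels by
descending size; each module's eigengene is the first principal component of
its standardized expression, and kME (module membership) is the correlation
of every gene with each eigengene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .io import CountMatrix
from .qc import lognormalize

__all__ = [
    "WgcnaParams",
    "CoexpressionModule",
    "MODULE_COLORS",
    "expr_frame",
    "make_metacells",
    "pick_soft_power",
    "adjacency_tom",
    "cut_modules",
    "eigengene_kme",
    "module_state_association",
]

# the standard WGCNA label sequence, assigned by descending module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
]
GREY = "grey"


@dataclass
class WgcnaParams:
    soft_power: int = 12
    min_module_size: int = 30
    cut_height: float = 0.995  # fraction of the dendrogram height range
    metacell_k: int = 25
    n_hub_genes: int = 25

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")


@dataclass
class CoexpressionModule:
    module_id: str
    members: list[str]
    eigengene: pd.Series
    kme: pd.Series  # over ALL genes
    hub_genes: list[str]


def expr_frame(cm: CountMatrix) -> pd.DataFrame:
    """Samples x genes DataFrame view of a (log-normalized) matrix."""
    return pd.DataFrame(cm.dense(), index=cm.cell_ids, columns=cm.gene_ids)


def make_metacells(
    cm: CountMatrix,
    embedding: pd.DataFrame,
    k: int = 25,
    lognorm: bool = True,
) -> tuple[CountMatrix, list[np.ndarray]]:
    """Aggregate counts over k-nearest-neighbor groups of cells.

    Greedy without replacement: take the first unused cell as a seed, pool
    it with its k-1 nearest unused neighbors (Euclidean distance in the
    embedding), repeat until fewer than k unused cells remain — yielding
    exactly floor(n/k) metacells. Counts are summed, then log-normalized
    unless ``lognorm=False``.
    """
    if cm.layer_tag != "counts":
        raise ValueError("make_metacells expects the counts layer")
    emb = embedding.reindex(cm.cell_ids).to_numpy()
    n = cm.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available cells")
    dist = ssd.squareform(ssd.pdist(emb))
    unused = np.ones(n, dtype=bool)
    groups: list[np.ndarray] = []
    while unused.sum() >= k:
        seed = int(np.flatnonzero(unused)[0])
        cand = np.flatnonzero(unused)
        nearest = cand[np.argsort(dist[seed, cand], kind="stable")[:k]]
        groups.append(nearest)
        unused[nearest] = False

    x = cm.values
    agg = np.vstack([np.asarray(x[g].sum(axis=0)).ravel() for g in groups])
    out = CountMatrix(
        values=agg.astype(np.int64),
        cell_ids=[f"metacell{i:04d}" for i in range(len(groups))],
        gene_ids=cm.gene_ids,
    )
    if lognorm:
        out = lognormalize(out)
    return out, groups


def _abs_cor(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    return np.abs(np.nan_to_num(r, nan=0.0))


def pick_soft_power(
    expression: pd.DataFrame,
    candidates: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft power reaching scale-free topology fit R^2 >= target.

    For each candidate beta the connectivity distribution p(k) is binned and
    log10 p(k) regressed on log10 k; the fit is sign-corrected (a negative
    slope is required for scale-free behavior). Falls back to the argmax
    R^2, with a warning, when no candidate reaches the target.
    """
    cor = _abs_cor(expression.to_numpy())
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in candidates:
        a = cor**beta
        k = a.sum(axis=0)
        rows.append({"beta": beta, "r2": _scale_free_r2(k, n_bins),
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_target]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(table.loc[table["r2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_target}; "
            f"falling back to argmax (beta={beta})"
        )
    return beta, table


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if len(k) < n_bins or np.allclose(k, k[0]):
        return -np.inf
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        kb = k[idx == b]
        if len(kb) == 0:
            continue
        log_k.append(np.log10(kb.mean()))
        log_p.append(np.log10(len(kb) / len(k)))
    if len(log_k) < 3:
        return -np.inf
    slope, _, r, _, _ = scipy.stats.linregress(log_k, log_p)
    return float(-np.sign(slope) * r**2)


def adjacency_tom(expression: pd.DataFrame, beta: int = 12) -> pd.DataFrame:
    """Topological overlap dissimilarity of the soft-thresholded network.

    a_ij = |pearson(x_i, x_j)|^beta with a_ii = 0;
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij);
    returned as 1 - TOM with zero diagonal.
    """
    a = _abs_cor(expression.to_numpy()) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    genes = expression.columns
    return pd.DataFrame(diss, index=genes, columns=genes)


def cut_modules(
    dissimilarity: pd.DataFrame, params: WgcnaParams | None = None
) -> pd.Series:
    """Average-linkage clustering of the TOM dissimilarity, static cut.

    The tree is cut at ``cut_height`` times the tallest merge; clusters
    smaller than ``min_module_size`` fall into the unassigned "grey" pool.
    Surviving modules are labeled with the WGCNA color sequence by
    descending size.
    """
    params = params or WgcnaParams()
    genes = dissimilarity.index
    condensed = ssd.squareform(dissimilarity.to_numpy(), checks=False)
    link = sch.linkage(condensed, method="average")
    t = params.cut_height * link[:, 2].max()
    raw = sch.fcluster(link, t=t, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    labels = pd.Series(GREY, index=genes, dtype="object", name="module")
    color_i = 0
    for cluster_id, size in sizes.items():
        if size < params.min_module_size:
            continue
        color = (
            MODULE_COLORS[color_i]
            if color_i < len(MODULE_COLORS)
            else f"module{color_i + 1}"
        )
        labels[np.asarray(raw == cluster_id)] = color
        color_i += 1
    return labels


def eigengene_kme(
    expression: pd.DataFrame,
    modules: pd.Series,
    n_hub_genes: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CoexpressionModule]]:
    """Module eigengenes, all-gene kME and per-module hub lists.

    The eigengene is the first principal component of the module's
    standardized expression, sign-fixed to correlate positively with the
    module's mean expression. kME(g, M) = pearson(x_g, eigengene_M), signed,
    for every gene against every module; hubs are the top module members by
    kME.
    """
    x = expression.to_numpy(dtype=float)
    mod_names = [m for m in modules.unique() if m != GREY]
    eigengenes = pd.DataFrame(index=expression.index, columns=mod_names, dtype=float)
    for m in mod_names:
        cols = np.flatnonzero((modules == m).to_numpy())
        sub = x[:, cols]
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        sub = sub / sd
        u, s, _ = np.linalg.svd(sub, full_matrices=False)
        eg = u[:, 0]
        if np.corrcoef(eg, sub.mean(axis=1))[0, 1] < 0:
            eg = -eg
        eigengenes[m] = eg

    centered = x - x.mean(axis=0)
    gene_sd = centered.std(axis=0)
    gene_sd[gene_sd == 0] = np.inf
    kme = pd.DataFrame(index=expression.columns, columns=mod_names, dtype=float)
    for m in mod_names:
        eg = eigengenes[m].to_numpy()
        egc = eg - eg.mean()
        kme[m] = (centered.T @ egc) / (len(eg) * gene_sd * egc.std())

    result: dict[str, CoexpressionModule] = {}
    for m in mod_names:
        members = list(expression.columns[(modules == m).to_numpy()])
        ranked = sorted(members, key=lambda g: -kme.loc[g, m])
        result[m] = CoexpressionModule(
            module_id=m,
            members=members,
            eigengene=eigengenes[m],
            kme=kme[m],
            hub_genes=ranked[: min(n_hub_genes, len(members))],
        )
    return eigengenes, kme, result


def module_state_association(
    eigengenes: pd.DataFrame, states: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis test of each eigengene across the lactylation states."""
    from statsmodels.stats.multitest import multipletests

    states = states.reindex(eigengenes.index)
    groups = [g for g in ("LLS", "LDTS", "LHS") if (states == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two states with cells")
    rows = []
    for m in eigengenes.columns:
        samples = [eigengenes.loc[(states == g).to_numpy(), m] for g in groups]
        stat, p = scipy.stats.kruskal(*samples)
        row = {"module": m, "kw_stat": float(stat), "p": float(p)}
        for g in groups:
            row[f"mean_{g}"] = float(eigengenes.loc[(states == g).to_numpy(), m].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
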