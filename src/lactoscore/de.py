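"""Differential expression between lactylation states and over-representation.

The LHS-vs-LLS contrast uses the Wilcoxon rank-sum test per gene (exact for
tiny tie-free groups, tie-corrected normal approximation otherwise) with the
Seurat-style log2 fold change, Benjamini-Hochberg adjustment over all tested
genes, and the protocol thresholds p < 0.01, |log2FC| > 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneSetCollection

__all__ = ["de_states", "intersect_genes", "ora_hypergeometric"]


def _seurat_log2fc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.log2(
        (np.expm1(a).mean(axis=0) + 1.0) / (np.expm1(b).mean(axis=0) + 1.0)
    )


def de_states(
    cm: CountMatrix,
    states: pd.Series,
    p_max: float = 0.01,
    lfc_min: float = 0.25,
    group_a: str = "LHS",
    group_b: str = "LLS",
) -> pd.DataFrame:
    """Per-gene rank-sum test of ``group_a`` vs ``group_b`` cells.

    Returns all tested genes with p, BH-adjusted p, log2FC and direction;
    the ``passing`` column marks genes with p < p_max and |log2FC| > lfc_min
    (both directions kept).
    """
    if cm.layer_tag != "lognorm":
        raise ValueError("de_states expects log-normalized values")
    states = states.reindex(cm.cell_ids)
    mask_a = (states == group_a).to_numpy()
    mask_b = (states == group_b).to_numpy()
    for name, mask in ((group_a, mask_a), (group_b, mask_b)):
        if not mask.any():
            raise ValueError(f"state {name!r} has no cells")

    x = cm.dense()
    a, b = x[mask_a], x[mask_b]
    if a.shape[0] <= 10 and b.shape[0] <= 10:
        from .qc import rank_sum_test

        p = np.array([rank_sum_test(a[:, j], b[:, j]) for j in range(x.shape[1])])
    else:
        p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", axis=0).pvalue
    lfc = _seurat_log2fc(a, b)
    p_adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )
    out["passing"] = (out["p"] < p_max) & (out["log2fc"].abs() > lfc_min)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def intersect_genes(a: list[str], b: list[str]) -> list[str]:
    """Order-stable intersection (order of ``a``), exact string match."""
    in_b = set(b)
    return [g for g in a if g in in_b]


def ora_hypergeometric(
    query: list[str],
    collection: GeneSetCollection,
    background: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    For each set: overlap k of query and set within the background of M
    genes; p = P(X >= k) for X hypergeometric(M, |set within background|,
    |query within background|); BH across sets.
    """
    if not query:
        raise ValueError("empty query gene list")
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    q = [g for g in dict.fromkeys(query) if g in bg_set]
    rows = []
    for gs in collection:
        members = [g for g in gs.genes if g in bg_set]
        overlap = len(set(q) & set(members))
        m, n_set, n_query = len(bg), len(members), len(q)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, m, n_set, n_query))
        rows.append(
            {
                "set_name": gs.name,
                "overlap": overlap,
                "set_size": n_set,
                "query_size": n_query,
                "background_size": m,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
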