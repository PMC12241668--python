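"""Five per-cell gene-set activity scorers.

All five quantify how strongly the members of a signature (here, the
lactylation-related genes) are expressed in each cell, but through different
statistics:

* ``aucell`` — area under the recovery curve: how many signature genes sit
  within the top-k ranked genes of the cell, integrated over the top ranks.
* ``ucell`` — a normalized Mann-Whitney U statistic of the signature's ranks,
  with ranks capped at ``ucell_max_rank``.
* ``singscore`` — the signature's mean rank, rescaled so 0 is the worst and
  1 the best achievable mean rank.
* ``ssgsea`` — an integrated, rank-weighted Kolmogorov-Smirnov-like running
  sum over the cell's full gene ranking.
* ``modulescore`` — mean signature expression minus the mean of
  expression-bin-matched control genes (the per-cell module score).

The first four are pure functions of the cell's gene ranking, hence
invariant under any strictly monotone transformation of expression. Ties are
resolved by average ranks throughout, so every scorer is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix, GeneSet

__all__ = [
    "ScoringParams",
    "rank_descending",
    "score_aucell",
    "score_ucell",
    "score_singscore",
    "score_ssgsea",
    "score_modulescore",
    "score_all",
    "METHODS",
]

METHODS = ("aucell", "ucell", "singscore", "ssgsea", "modulescore")


@dataclass
class ScoringParams:
    auc_max_rank_fraction: float = 0.05
    ucell_max_rank: int = 1500
    ssgsea_alpha: float = 0.25
    module_n_bins: int = 24
    module_n_controls: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.auc_max_rank_fraction <= 1:
            raise ValueError("auc_max_rank_fraction must be in (0,1]")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.ucell_max_rank < 1:
            raise ValueError("ucell_max_rank must be positive")


def rank_descending(expression: np.ndarray) -> np.ndarray:
    """Dense average ranks by descending expression; rank 1 = highest.

    Works on a single cell (1-D) or a cells x genes matrix (ranks per row).
    """
    expression = np.asarray(expression, dtype=float)
    axis = expression.ndim - 1
    return scipy.stats.rankdata(-expression, method="average", axis=axis)


def _as_2d(ranks: np.ndarray) -> tuple[np.ndarray, bool]:
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim == 1:
        return ranks[None, :], True
    return ranks, False


def score_aucell(
    ranks: np.ndarray, set_idx: np.ndarray, max_rank_fraction: float = 0.05
) -> np.ndarray | float:
    """Normalized area under the signature's rank-recovery curve.

    With H(x) = number of signature genes at rank <= x and k =
    ceil(fraction * N), the score is sum_{x=1..k} H(x) divided by its
    maximum sum_{x=1..k} min(x, n_s); 1 iff the signature occupies the top
    n_s ranks, 0 if it lies entirely below rank k.
    """
    r, squeeze = _as_2d(ranks)
    n = r.shape[1]
    k = int(np.ceil(max_rank_fraction * n))
    n_s = len(set_idx)
    sr = np.ceil(r[:, set_idx])  # a tied rank counts from the next integer
    num = np.maximum(0.0, k - sr + 1.0).sum(axis=1)
    x = np.arange(1, k + 1)
    denom = np.minimum(x, n_s).sum()
    out = num / denom
    return float(out[0]) if squeeze else out


def score_ucell(
    ranks: np.ndarray, set_idx: np.ndarray, max_rank: int = 1500
) -> np.ndarray | float:
    """1 - U/(n_s * r_max) with signature ranks capped at r_max + 1."""
    r, squeeze = _as_2d(ranks)
    n_s = len(set_idx)
    capped = np.minimum(r[:, set_idx], max_rank + 1)
    u = capped.sum(axis=1) - n_s * (n_s + 1) / 2.0
    out = np.clip(1.0 - u / (n_s * max_rank), 0.0, 1.0)
    return float(out[0]) if squeeze else out


def score_singscore(ranks: np.ndarray, set_idx: np.ndarray) -> np.ndarray | float:
    """Mean signature rank rescaled to [0,1] over its achievable range.

    Uses ascending ranks (N = most expressed): with mr the signature's mean
    ascending rank, score = (mr - (n_s+1)/2) / (N - (n_s-1)/2 - (n_s+1)/2).
    """
    r, squeeze = _as_2d(ranks)
    n = r.shape[1]
    n_s = len(set_idx)
    ascending = n + 1.0 - r[:, set_idx]
    mr = ascending.mean(axis=1)
    lo = (n_s + 1) / 2.0
    hi = n - (n_s - 1) / 2.0
    out = (mr - lo) / (hi - lo)
    return float(out[0]) if squeeze else out


def score_ssgsea(
    ranks: np.ndarray, set_idx: np.ndarray, alpha: float = 0.25
) -> np.ndarray | float:
    """Integrated weighted running-sum enrichment over the full ranking.

    Genes are walked from the most to the least expressed; a signature gene
    at rank r adds (N - r + 1)^alpha normalized by the signature's total
    weight, every other gene subtracts 1/(N - n_s). The score is the sum of
    the running sum over all N steps.
    """
    r, squeeze = _as_2d(ranks)
    n_cells, n = r.shape
    n_s = len(set_idx)
    in_set = np.zeros(n, dtype=bool)
    in_set[set_idx] = True

    order = np.argsort(r, axis=1, kind="stable")  # ties: stable gene order
    in_set_ordered = in_set[order]
    weight = (n - r + 1.0) ** alpha
    w_ordered = np.take_along_axis(weight, order, axis=1)
    w_set = np.where(in_set_ordered, w_ordered, 0.0)
    w_tot = w_set.sum(axis=1, keepdims=True)
    steps = np.where(
        in_set_ordered, w_set / w_tot, -1.0 / (n - n_s)
    )
    es = np.cumsum(steps, axis=1).sum(axis=1)
    return float(es[0]) if squeeze else es


def score_modulescore(
    cm: CountMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Signature mean expression minus bin-matched control mean, per cell.

    Genes are binned into ``n_bins`` by average expression across cells; for
    each signature gene, ``n_controls`` control genes are drawn from its bin
    (without replacement when the bin is large enough). The draw is seeded,
    so scores are reproducible.
    """
    if cm.layer_tag != "lognorm":
        raise ValueError("score_modulescore expects log-normalized values")
    x = cm.dense()
    set_idx = cm.gene_index(gene_set.genes)
    if len(set_idx) == 0:
        warnings.warn(f"gene set {gene_set.name!r}: no members in matrix")
        return pd.Series(np.nan, index=cm.cell_ids, name="modulescore")

    mean = x.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    n_genes = cm.n_genes
    bins = np.empty(n_genes, dtype=int)
    n_bins = min(n_bins, n_genes)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
    )

    rng = np.random.default_rng(seed)
    control_idx: list[np.ndarray] = []
    for g in set_idx:
        pool = np.flatnonzero(bins == bins[g])
        replace = len(pool) < n_controls
        control_idx.append(rng.choice(pool, size=n_controls, replace=replace))
    controls = np.concatenate(control_idx)

    score = x[:, set_idx].mean(axis=1) - x[:, controls].mean(axis=1)
    return pd.Series(score, index=cm.cell_ids, name="modulescore")


def match_gene_set(
    gene_set: GeneSet, gene_ids: np.ndarray
) -> tuple[np.ndarray, float]:
    """Indices of signature members present in the matrix + matched fraction.

    Matching is exact-string and case-sensitive; a matched fraction below
    0.5 raises a prominent warning (usually a symbol-case problem).
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([lookup[g] for g in gene_set.genes if g in lookup], dtype=int)
    frac = len(idx) / len(gene_set.genes)
    if 0 < frac < 0.5:
        warnings.warn(
            f"gene set {gene_set.name!r}: only {frac:.1%} of members matched "
            "the matrix — check gene-symbol namespace and case"
        )
    return idx, frac


def score_all(
    cm: CountMatrix,
    gene_set: GeneSet,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Raw per-cell scores for all five methods (columns = method names).

    Expects log-normalized expression. Unmatched signature members are
    dropped globally; if nothing matches, all scores are missing.
    """
    params = params or ScoringParams()
    if cm.layer_tag != "lognorm":
        raise ValueError("score_all expects log-normalized values")
    set_idx, frac = match_gene_set(gene_set, cm.gene_ids)
    panel = pd.DataFrame(index=pd.Index(cm.cell_ids, name="cell_id"),
                         columns=list(METHODS), dtype=float)
    if len(set_idx) == 0:
        warnings.warn(
            f"gene set {gene_set.name!r}: zero matched genes; scores missing"
        )
        return panel
    if params.ucell_max_rank < len(set_idx):
        raise ValueError("ucell_max_rank must be >= matched set size")

    ranks = rank_descending(cm.dense())
    panel["aucell"] = score_aucell(ranks, set_idx, params.auc_max_rank_fraction)
    panel["ucell"] = score_ucell(ranks, set_idx, params.ucell_max_rank)
    panel["singscore"] = score_singscore(ranks, set_idx)
    panel["ssgsea"] = score_ssgsea(ranks, set_idx, params.ssgsea_alpha)
    panel["modulescore"] = score_modulescore(
        cm, gene_set, params.module_n_bins, params.module_n_controls, params.seed
    ).to_numpy()
    return panel
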