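"""Consensus score fusion and IQR-based lactylation-state assignment.

Each scorer's raw output is min-max normalized to [0,1]; the per-cell
consensus is their unweighted mean (median available as an option). Cells are
then stratified by the consensus distribution's quartiles: below the 25th
percentile = low lactylation state (LLS), above the 75th = high (LHS),
everything between = dynamic transition (LDTS).

Quantile convention: q25 is the (floor(n/4)+1)-th and q75 the ceil(3n/4)-th
order statistic, with strict inequalities at the boundaries. With all-distinct
scores this puts exactly floor(n/4) cells in LLS and n - ceil(3n/4) in LHS
(n/4 each when n is divisible by 4); boundary ties fall into LDTS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet
from .scoring import METHODS, ScoringParams, score_all

__all__ = [
    "STATES",
    "IqrBounds",
    "minmax_normalize",
    "consensus",
    "assign_states",
    "build_panel",
    "score_spatial",
]

STATES = ("LLS", "LDTS", "LHS")


@dataclass
class IqrBounds:
    q25: float
    q75: float
    quantile_convention: str = "order-statistic(lower-hinge=floor(n/4)+1, upper-hinge=ceil(3n/4))"

    def __post_init__(self) -> None:
        if self.q25 > self.q75:
            raise ValueError("q25 > q75")


def minmax_normalize(raw: pd.Series) -> pd.Series:
    """(x - min)/(max - min); a constant vector maps to 0.5 everywhere."""
    x = raw.astype(float)
    finite = x.dropna()
    if finite.empty:
        return x
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn(f"{raw.name or 'score'}: constant vector, normalized to 0.5")
        return x.where(x.isna(), 0.5)
    return (x - lo) / (hi - lo)


def consensus(norm_panel: pd.DataFrame, how: str = "mean") -> pd.Series:
    """Per-cell fusion of the normalized scores over non-missing methods."""
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    fused = norm_panel.mean(axis=1) if how == "mean" else norm_panel.median(axis=1)
    all_missing = norm_panel.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} cell(s) missing every score; "
            "excluded from state assignment"
        )
        fused[all_missing] = np.nan
    return fused.rename("consensus")


def assign_states(scores: pd.Series) -> tuple[pd.Series, IqrBounds]:
    """Stratify cells into LLS / LDTS / LHS by consensus-score quartiles."""
    valid = scores.dropna()
    n = len(valid)
    if n < 8:
        raise ValueError(f"state assignment needs >= 8 scored cells, got {n}")
    s = np.sort(valid.to_numpy())
    q25 = float(s[n // 4])              # (floor(n/4)+1)-th order statistic
    q75 = float(s[int(np.ceil(3 * n / 4)) - 1])  # ceil(3n/4)-th
    bounds = IqrBounds(q25=q25, q75=q75)

    states = pd.Series(pd.NA, index=scores.index, dtype="object", name="state")
    states[scores < bounds.q25] = "LLS"
    states[scores > bounds.q75] = "LHS"
    middle = scores.notna() & states.isna()
    states[middle] = "LDTS"
    if (states.dropna() == "LDTS").all() and q25 == q75:
        warnings.warn("degenerate consensus distribution: every cell is LDTS")
    return states, bounds


def build_panel(
    raw_panel: pd.DataFrame, how: str = "mean"
) -> tuple[pd.DataFrame, IqrBounds]:
    """Raw scores -> normalized scores, consensus and state, as one table."""
    panel = raw_panel.copy()
    for m in METHODS:
        if m in panel:
            panel[f"{m}_norm"] = minmax_normalize(panel[m])
    norm = panel[[f"{m}_norm" for m in METHODS if f"{m}_norm" in panel]]
    panel["consensus"] = consensus(norm, how=how)
    states, bounds = assign_states(panel["consensus"])
    panel["state"] = states
    return panel, bounds


def score_spatial(
    counts: CountMatrix,
    coords: pd.DataFrame,
    gene_set: GeneSet,
    params: ScoringParams | None = None,
    how: str = "mean",
) -> tuple[pd.DataFrame, IqrBounds]:
    """Apply the full scoring -> consensus -> state machinery to spots.

    ``counts`` may be raw counts (log-normalized internally). The returned
    table carries the spot coordinates alongside scores and states.
    """
    from .qc import lognormalize

    if counts.layer_tag == "counts":
        counts = lognormalize(counts)
    raw = score_all(counts, gene_set, params)
    panel, bounds = build_panel(raw, how=how)
    coords = coords.set_index("spot_id")
    joined = panel.join(coords.reindex(panel.index))
    return joined, bounds
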