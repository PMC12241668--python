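"""Synthetic transcriptomics generators with planted ground truth.

Every input the pipeline consumes can be produced here: overdispersed
(negative-binomial) single-cell counts with cell-type structure, mitochondrial
genes and a planted high-lactylation subpopulation; block-correlated
expression for co-expression module recovery; a labeled survival cohort with
planted informative genes; and a spatial grid with a planted high-activity
region. All generators are pure functions of their configuration, seed
included: one global seed drives named sub-streams so adding an output does
not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import CohortTable
from .io import CountMatrix

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "GroundTruth",
    "SpatialMatrix",
    "simulate_sc_counts",
    "simulate_modular_expression",
    "simulate_cohort",
    "simulate_spatial",
]

# fixed stream ids so each output draws from its own independent substream
_STREAMS = {
    "sc": 1,
    "modular": 2,
    "cohort": 3,
    "spatial": 4,
    "controls": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named output stream of one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class CohortSpec:
    n_samples: int = 500
    n_genes: int = 100
    n_informative: int = 3
    effect_size: float = 1.5  # per-gene coefficient on standardized expression
    censoring_rate: float = 0.3


@dataclass
class SimulationConfig:
    n_cells: int = 2000
    n_genes: int = 3000
    n_celltypes: int = 4
    lactylation_set_size: int = 50
    lhs_fraction: float = 0.25
    lactylation_fold: float = 4.0
    mito_fraction_range: tuple[float, float] = (0.02, 0.15)
    nb_dispersion: float = 0.5
    n_mito_genes: int = 10
    markers_per_type: int = 30
    celltype_fold: float = 4.0
    module_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(50, 0.8), (50, 0.8)]
    )
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.lhs_fraction < 1:
            raise ValueError("lhs_fraction must be in (0,1)")
        if self.lactylation_fold < 1:
            raise ValueError("lactylation_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.mito_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 < lo <= hi < 1")
        if sum(m for m, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for _, rho in self.module_spec:
            if not 0 <= rho < 1:
                raise ValueError("within-module correlation must be in [0,1)")

    def validate_sc(self) -> None:
        self.validate()
        n_special = (
            self.lactylation_set_size
            + self.n_mito_genes
            + self.n_celltypes * self.markers_per_type
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"signature + mito + marker genes ({n_special}) exceed n_genes "
                f"({self.n_genes})"
            )


@dataclass
class GroundTruth:
    planted_high_cells: set[str] = field(default_factory=set)
    signature_genes: set[str] = field(default_factory=set)
    celltype_assignments: dict[str, int] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    informative_cohort_genes: set[str] = field(default_factory=set)
    planted_region_spots: set[str] = field(default_factory=set)


@dataclass
class SpatialMatrix:
    counts: CountMatrix
    coords: pd.DataFrame  # columns: spot_id, x, y


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """NB draw with var = m + dispersion * m^2 (size r = 1/dispersion)."""
    r = 1.0 / dispersion
    mean = np.clip(mean, 1e-12, None)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_sc_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial single-cell counts with planted structure.

    Gene baseline means are log-normal. Cells belong to one of
    ``n_celltypes`` types, each over-expressing a disjoint marker block by
    ``celltype_fold``. A planted ``lhs_fraction`` of cells multiplies the
    designated lactylation signature genes by ``lactylation_fold``.
    Mitochondrial genes carry an "MT-" prefix and contribute a per-cell
    fraction of counts drawn uniformly from ``mito_fraction_range``.
    """
    config.validate_sc()
    rng = stream_rng(config.seed, "sc")
    n_c, n_g = config.n_cells, config.n_genes

    n_mito = config.n_mito_genes
    n_sig = config.lactylation_set_size
    gene_ids = np.array(
        [f"MT-{i + 1}" for i in range(n_mito)]
        + [f"LACT{i:04d}" for i in range(n_sig)]
        + _gene_names(n_g - n_mito - n_sig),
        dtype=object,
    )
    mito_idx = np.arange(n_mito)
    sig_idx = np.arange(n_mito, n_mito + n_sig)
    free_idx = np.arange(n_mito + n_sig, n_g)

    cell_ids = np.array([f"cell{i:05d}" for i in range(n_c)], dtype=object)
    celltype = rng.integers(0, config.n_celltypes, size=n_c)
    high = rng.random(n_c) < config.lhs_fraction

    base = rng.lognormal(mean=np.log(0.3), sigma=1.0, size=n_g)
    # signature genes are moderately expressed (metabolic-enzyme-like), so
    # the planted fold is not censored by dropout
    base[sig_idx] = rng.lognormal(mean=0.0, sigma=0.5, size=n_sig)
    base[mito_idx] = 0.0  # filled per cell below

    # disjoint cell-type marker blocks among the unreserved genes
    marker_blocks = [
        free_idx[t * config.markers_per_type : (t + 1) * config.markers_per_type]
        for t in range(config.n_celltypes)
    ]

    mean = np.tile(base, (n_c, 1))
    for t, block in enumerate(marker_blocks):
        mean[np.ix_(celltype == t, block)] *= config.celltype_fold
    mean[np.ix_(high, sig_idx)] *= config.lactylation_fold

    # per-cell mitochondrial share of total counts
    lo, hi = config.mito_fraction_range
    mito_frac = rng.uniform(lo, hi, size=n_c)
    non_mito_total = mean.sum(axis=1)
    mean[:, mito_idx] = (
        mito_frac / (1 - mito_frac) * non_mito_total / n_mito
    )[:, None]

    # mild library-size variation
    libsize = rng.lognormal(mean=0.0, sigma=0.25, size=n_c)
    mean *= libsize[:, None]

    counts = _nb_sample(rng, mean, config.nb_dispersion)
    cm = CountMatrix(
        values=sp.csr_matrix(counts), cell_ids=cell_ids, gene_ids=gene_ids
    )
    truth = GroundTruth(
        planted_high_cells=set(cell_ids[high]),
        signature_genes=set(gene_ids[sig_idx]),
        celltype_assignments=dict(zip(cell_ids, celltype.tolist())),
    )
    return cm, truth


def simulate_modular_expression(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Block-correlated expression for module-recovery benchmarks.

    Each module m of size s with target within-correlation rho is generated
    from a shared latent factor: x = mu + sqrt(rho) z_m + sqrt(1-rho) eps, so
    the expected pairwise Pearson r inside the module is rho and ~0 outside.
    Values are continuous and treated as log-normalized expression.
    """
    config.validate()
    rng = stream_rng(config.seed, "modular")
    n_c, n_g = config.n_cells, config.n_genes
    gene_ids = np.array(_gene_names(n_g), dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_c)], dtype=object)

    x = rng.normal(0.0, 1.0, size=(n_c, n_g))
    assignments: dict[str, int] = {}
    start = 0
    for m, (size, rho) in enumerate(config.module_spec):
        factor = rng.normal(0.0, 1.0, size=n_c)
        block = slice(start, start + size)
        x[:, block] = np.sqrt(rho) * factor[:, None] + np.sqrt(1 - rho) * x[:, block]
        for g in gene_ids[block]:
            assignments[g] = m
        start += size

    x = np.clip(x + 10.0, 0.0, None)  # shift into non-negative expression space
    cm = CountMatrix(
        values=sp.csr_matrix(x),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        layer_tag="lognorm",
    )
    return cm, GroundTruth(module_assignments=assignments)


def simulate_cohort(
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    informative_genes: Sequence[str] | None = None,
) -> tuple[CohortTable, GroundTruth]:
    """Labeled survival cohort with planted informative genes.

    Expression is standard normal. The binary label follows a logistic model
    whose log-odds is ``effect_size`` times the sum of informative-gene
    values; survival times are exponential with the same linear predictor as
    log-hazard, independently censored at the configured expected rate.
    """
    spec = config.cohort_spec
    rng = stream_rng(config.seed, "cohort")
    if genes is None:
        genes = [f"CG{i:04d}" for i in range(spec.n_genes)]
    genes = list(genes)
    if informative_genes is None:
        informative_genes = list(
            rng.choice(np.asarray(genes, dtype=object), size=spec.n_informative,
                       replace=False)
        )
    informative_genes = list(informative_genes)
    missing = set(informative_genes) - set(genes)
    if missing:
        raise ValueError(f"informative genes not in cohort genes: {sorted(missing)}")

    n = spec.n_samples
    x = rng.normal(0.0, 1.0, size=(n, len(genes)))
    expr = pd.DataFrame(
        x, index=[f"sample{i:04d}" for i in range(n)], columns=genes
    )
    lin = spec.effect_size * expr[informative_genes].sum(axis=1).to_numpy()

    p = 1.0 / (1.0 + np.exp(-lin))
    label = (rng.random(n) < p).astype(int)

    base_rate = 0.1
    hazard = base_rate * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        rate_c = hazard.mean() * spec.censoring_rate / (1 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = CohortTable(
        expression=expr,
        label=pd.Series(label, index=expr.index),
        time=pd.Series(np.clip(time, 1e-9, None), index=expr.index),
        event=pd.Series(event, index=expr.index),
    )
    return cohort, GroundTruth(informative_cohort_genes=set(informative_genes))


def simulate_spatial(config: SimulationConfig) -> tuple[SpatialMatrix, GroundTruth]:
    """Spot grid with a contiguous planted high-activity ("tumor") region.

    The grid side is ``ceil(sqrt(n_cells))`` (n_cells doubles as spot count);
    a central square holding roughly ``lhs_fraction`` of spots over-expresses
    the signature genes by ``lactylation_fold``.
    """
    config.validate()
    if config.lactylation_set_size > config.n_genes:
        raise ValueError("lactylation_set_size exceeds n_genes")
    rng = stream_rng(config.seed, "spatial")
    side = int(np.ceil(np.sqrt(config.n_cells)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    xs, ys = xs.ravel()[: config.n_cells], ys.ravel()[: config.n_cells]
    spot_ids = np.array([f"spot_{x}_{y}" for x, y in zip(xs, ys)], dtype=object)

    half = max(1, int(round(side * np.sqrt(config.lhs_fraction) / 2)))
    cx = cy = side // 2
    in_region = (
        (np.abs(xs - cx) < half) & (np.abs(ys - cy) < half)
    )

    n_g = config.n_genes
    n_sig = config.lactylation_set_size
    gene_ids = np.array(
        [f"LACT{i:04d}" for i in range(n_sig)] + _gene_names(n_g - n_sig),
        dtype=object,
    )
    base = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=n_g)
    mean = np.tile(base, (len(spot_ids), 1))
    mean[np.ix_(in_region, np.arange(n_sig))] *= config.lactylation_fold
    counts = _nb_sample(rng, mean, config.nb_dispersion)

    cm = CountMatrix(
        values=sp.csr_matrix(counts), cell_ids=spot_ids, gene_ids=gene_ids
    )
    coords = pd.DataFrame({"spot_id": spot_ids, "x": xs, "y": ys})
    truth = GroundTruth(
        planted_region_spots=set(spot_ids[in_region]),
        signature_genes=set(gene_ids[:n_sig]),
    )
    return SpatialMatrix(counts=cm, coords=coords), truth
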