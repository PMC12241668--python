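"""End-to-end orchestration: QC -> scoring -> states -> DE -> modules ->
overlap -> feature selection, with a one-command synthetic demo.

Every stage writes its table under the run directory and the manifest
records seeds, thresholds and per-stage row counts, so each stage can be
re-run from its on-disk inputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import featsel, io, qc, scoring, states, synth, wgcna

__all__ = ["RunConfig", "run_pipeline", "demo"]

log = logging.getLogger("lactoscore")


@dataclass
class RunConfig:
    out_dir: str = "lactoscore_run"
    seed: int = 0
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    hvg_pca: qc.HvgPcaParams = field(default_factory=qc.HvgPcaParams)
    cluster_resolution: float = 0.8
    scoring: scoring.ScoringParams = field(default_factory=scoring.ScoringParams)
    consensus_how: str = "mean"
    de_p_max: float = 0.01
    de_lfc_min: float = 0.25
    wgcna: wgcna.WgcnaParams = field(default_factory=wgcna.WgcnaParams)
    wgcna_n_genes: int = 1000  # network built on this many top HVGs
    module_p_adj_max: float = 0.05
    lasso_repeats: int = 3  # CV repeats at demo scale; select_lasso defaults to 10
    rf_trees: int = 500
    boruta_trees: int = 150


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    io.write_table(df, path)
    manifest["row_counts"][path.name] = len(df)


def run_pipeline(
    config: RunConfig,
    counts: io.CountMatrix,
    gene_set: io.GeneSet,
    cohort: "object | None" = None,
    truth: synth.GroundTruth | None = None,
) -> dict:
    """Execute the full pipeline on a count matrix and signature gene set.

    If ``cohort`` is None, a synthetic cohort is generated over the
    candidate genes emerging from the DEG/module overlap (the demo path).
    Returns the manifest dict; all tables live under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "row_counts": {},
        "parameters": {
            "qc": asdict(config.qc_thresholds),
            "hvg_pca": asdict(config.hvg_pca),
            "cluster_resolution": config.cluster_resolution,
            "scoring": asdict(config.scoring),
            "consensus_how": config.consensus_how,
            "de": {"p_max": config.de_p_max, "lfc_min": config.de_lfc_min},
            "wgcna": asdict(config.wgcna),
            "signature_size": len(gene_set),
        },
    }

    # ---- QC, normalization, HVG, PCA, clustering
    log.info("QC thresholds: %s", config.qc_thresholds)
    filtered, qc_report = qc.apply_qc(counts, config.qc_thresholds)
    _write(qc_report.to_frame(), out / "qc_report.tsv", manifest)
    norm = qc.lognormalize(filtered)
    hvgs = qc.select_hvgs(norm, config.hvg_pca.n_hvgs)
    log.info("selected %d HVGs", len(hvgs))
    embedding = qc.run_pca(norm, hvgs, config.hvg_pca.n_pcs)
    clusters = qc.cluster_cells(
        embedding, resolution=config.cluster_resolution, seed=config.seed
    )
    cl = clusters.rename_axis("cell_id").reset_index(name="cluster")
    _write(cl, out / "clusters.tsv", manifest)
    manifest["n_clusters"] = int(clusters.nunique())

    # ---- scoring, consensus, states
    raw = scoring.score_all(norm, gene_set, config.scoring)
    panel, bounds = states.build_panel(raw, how=config.consensus_how)
    _write(panel.reset_index(), out / "score_panel.tsv", manifest)
    manifest["iqr_bounds"] = {"q25": bounds.q25, "q75": bounds.q75}
    state_vec = panel["state"]
    manifest["state_counts"] = state_vec.value_counts().to_dict()
    log.info("state counts: %s", manifest["state_counts"])

    # ---- LHS vs LLS differential expression
    de_table = de_mod.de_states(
        norm, state_vec, p_max=config.de_p_max, lfc_min=config.de_lfc_min
    )
    _write(de_table, out / "de_lhs_vs_lls.tsv", manifest)
    degs_up = de_table.loc[
        de_table["passing"] & (de_table["direction"] == "up"), "gene"
    ].tolist()
    manifest["n_degs"] = int(de_table["passing"].sum())
    manifest["n_degs_up"] = len(degs_up)

    # ---- co-expression modules on metacells over top HVGs
    meta, _ = wgcna.make_metacells(filtered, embedding, k=config.wgcna.metacell_k)
    net_genes = [g for g in hvgs if g in set(meta.gene_ids)][: config.wgcna_n_genes]
    expr = wgcna.expr_frame(meta)[net_genes]
    beta, power_table = wgcna.pick_soft_power(expr)
    _write(power_table, out / "soft_power.tsv", manifest)
    manifest["soft_power"] = beta
    diss = wgcna.adjacency_tom(expr, beta=beta)
    modules = wgcna.cut_modules(diss, config.wgcna)
    _write(
        modules.rename_axis("gene").reset_index(name="module"),
        out / "modules.tsv",
        manifest,
    )
    if (modules == wgcna.GREY).all():
        raise RuntimeError(
            "module stage: no co-expression modules found (all genes "
            "unassigned); lower min_module_size or raise wgcna_n_genes"
        )
    eigengenes, kme, mod_objs = wgcna.eigengene_kme(
        expr, modules, n_hub_genes=config.wgcna.n_hub_genes
    )
    hubs = pd.DataFrame(
        [
            {"module": m, "rank": i + 1, "gene": g}
            for m, obj in mod_objs.items()
            for i, g in enumerate(obj.hub_genes)
        ]
    )
    _write(hubs, out / "hub_genes.tsv", manifest)

    # metacell states: score metacells with the same machinery
    meta_panel, _ = states.build_panel(
        scoring.score_all(meta, gene_set, config.scoring), how=config.consensus_how
    )
    assoc = wgcna.module_state_association(eigengenes, meta_panel["state"])
    _write(assoc, out / "module_state_association.tsv", manifest)

    # LHS-associated modules: significant and highest mean eigengene in LHS
    mean_cols = [c for c in assoc.columns if c.startswith("mean_")]
    lhs_modules = assoc.loc[
        (assoc["p_adj"] < config.module_p_adj_max)
        & (assoc[mean_cols].idxmax(axis=1) == "mean_LHS"),
        "module",
    ].tolist()
    manifest["lhs_modules"] = lhs_modules
    module_genes: list[str] = []
    for m in lhs_modules:
        module_genes.extend(mod_objs[m].members)

    # ---- overlap: up-DEGs also found in LHS-associated modules
    candidates = de_mod.intersect_genes(degs_up, module_genes)
    manifest["n_overlap_genes"] = len(candidates)
    io.write_table(
        pd.DataFrame({"gene": candidates}), out / "overlap_genes.tsv"
    )
    log.info("%d up-DEGs overlap LHS-associated modules", len(candidates))

    # ---- machine-learning hub-gene selection on the cohort
    if cohort is None:
        if not candidates:
            raise RuntimeError("overlap stage produced no candidate genes")
        cfg = synth.SimulationConfig(
            seed=config.seed, cohort_spec=config.sim.cohort_spec
        )
        n_inf = min(cfg.cohort_spec.n_informative, len(candidates))
        inf_rng = synth.stream_rng(config.seed, "cohort")
        informative = sorted(
            inf_rng.choice(np.asarray(candidates, dtype=object), size=n_inf,
                           replace=False).tolist()
        )
        cohort, cohort_truth = synth.simulate_cohort(
            cfg, genes=candidates, informative_genes=informative
        )
        manifest["planted_cohort_genes"] = sorted(
            cohort_truth.informative_cohort_genes
        )
    report = featsel.run_feature_selection(
        cohort,
        candidate_genes=candidates,
        seed=config.seed,
        lasso_repeats=config.lasso_repeats,
        rf_trees=config.rf_trees,
        boruta_trees=config.boruta_trees,
    )
    for name, genes in report.selections.items():
        io.write_table(pd.DataFrame({"gene": genes}), out / f"selected_{name}.tsv")
        manifest["row_counts"][f"selected_{name}.tsv"] = len(genes)
    io.write_table(
        pd.DataFrame({"gene": report.intersection}), out / "hub_intersection.tsv"
    )
    manifest["hub_genes"] = report.intersection

    if truth is not None:
        planted = truth.signature_genes & set(de_table["gene"])
        recovered = planted & set(degs_up)
        manifest["signature_de_recovery"] = (
            len(recovered) / len(planted) if planted else float("nan")
        )
        lhs_cells = set(state_vec[state_vec == "LHS"].index)
        planted_cells = truth.planted_high_cells & set(state_vec.index)
        manifest["lhs_recall"] = (
            len(lhs_cells & planted_cells) / len(planted_cells)
            if planted_cells
            else float("nan")
        )

    io.write_json(manifest, out / "manifest.json")
    return manifest


def run_from_files(
    config: RunConfig,
    matrix_path: str,
    genes_path: str,
    barcodes_path: str,
    gmt_path: str,
    set_name: str | None = None,
    cohort_path: str | None = None,
) -> dict:
    """Load on-disk inputs and execute the pipeline.

    A missing or unreadable input aborts naming the offending path.
    """
    from pathlib import Path as _P

    from .cohort import CohortTable

    for p in (matrix_path, genes_path, barcodes_path, gmt_path, cohort_path):
        if p is not None and not _P(p).exists():
            raise FileNotFoundError(f"pipeline input not found: {p}")
    counts = io.read_counts_triplet(matrix_path, genes_path, barcodes_path)
    collection = io.read_gmt(gmt_path)
    gene_set = collection[set_name] if set_name else collection.sets[0]
    cohort = CohortTable.from_tsv(cohort_path) if cohort_path else None
    return run_pipeline(config, counts, gene_set, cohort=cohort)


def demo(seed: int = 0, out_dir: str | None = None, **config_kwargs) -> dict:
    """Generate the default synthetic dataset and run the full pipeline.

    Defaults: 2000 cells, 3000 genes, a 50-gene signature at fold 4 in a
    planted 25% of cells, plus a 500-sample cohort with 3 informative genes
    at effect 1.5 SD.
    """
    config = RunConfig(
        out_dir=out_dir or f"lactoscore_demo_seed{seed}",
        seed=seed,
        **config_kwargs,
    )
    config.sim.seed = seed
    counts, truth = synth.simulate_sc_counts(config.sim)
    gene_set = io.GeneSet(
        name="lactylation_signature",
        genes=sorted(truth.signature_genes),
        description="planted synthetic lactylation signature",
    )
    return run_pipeline(config, counts, gene_set, truth=truth)
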