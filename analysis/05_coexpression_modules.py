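#!/usr/bin/env python
"""Metacell-based co-expression network: soft threshold, TOM, modules,
eigengenes, kME hubs, and association of each module with the lactylation
states.

Reads results/data|qc|states/, writes results/modules/ (membership,
eigengenes, hub genes, state association) and results/overlap_genes.tsv —
the up-regulated DEGs that also belong to LHS-associated modules, the
candidate pool for the machine-learning stage.
"""

import json
from pathlib import Path

import pandas as pd

from lactoscore import de, io, qc, scoring, states, wgcna

DATA = Path("results/data")
OUT = Path("results/modules")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts_triplet(
        DATA / "matrix.mtx", DATA / "genes.tsv", DATA / "barcodes.tsv"
    )
    filtered, _ = qc.apply_qc(counts)
    norm = qc.lognormalize(filtered)
    emb = io.read_table(Path("results/qc") / "pca_embedding.tsv").set_index(
        "cell_id"
    )
    params = wgcna.WgcnaParams()

    meta, _ = wgcna.make_metacells(filtered, emb, k=params.metacell_k)
    hvgs = qc.select_hvgs(norm, 1000)
    expr = wgcna.expr_frame(meta)[[g for g in hvgs if g in set(meta.gene_ids)]]
    beta, power_table = wgcna.pick_soft_power(expr)
    io.write_table(power_table, OUT / "soft_power.tsv")
    print(f"{len(meta.cell_ids)} metacells (k={params.metacell_k}); "
          f"soft power {beta} "
          f"(R^2={power_table.set_index('beta').loc[beta, 'r2']:.2f})")

    diss = wgcna.adjacency_tom(expr, beta=beta)
    modules = wgcna.cut_modules(diss, params)
    modules.rename_axis("gene").reset_index(name="module").pipe(
        io.write_table, OUT / "module_membership.tsv"
    )
    sizes = modules[modules != "grey"].value_counts()
    print(f"{len(sizes)} modules:", dict(sizes))

    eigengenes, kme, objs = wgcna.eigengene_kme(
        expr, modules, n_hub_genes=params.n_hub_genes
    )
    hubs = pd.DataFrame(
        [{"module": m, "rank": i + 1, "gene": g}
         for m, o in objs.items() for i, g in enumerate(o.hub_genes)]
    )
    io.write_table(hubs, OUT / "hub_genes.tsv")

    signature = io.read_gmt(DATA / "signature.gmt").sets[0]
    meta_panel, _ = states.build_panel(scoring.score_all(meta, signature))
    assoc = wgcna.module_state_association(eigengenes, meta_panel["state"])
    io.write_table(assoc, OUT / "module_state_association.tsv")
    mean_cols = [c for c in assoc.columns if c.startswith("mean_")]
    lhs_mods = assoc.loc[
        (assoc["p_adj"] < 0.05)
        & (assoc[mean_cols].idxmax(axis=1) == "mean_LHS"), "module",
    ].tolist()
    print("LHS-associated modules:", lhs_mods)

    de_table = io.read_table(Path("results/de") / "de_lhs_vs_lls.tsv")
    up = de_table.loc[
        de_table["passing"] & (de_table["direction"] == "up"), "gene"
    ].tolist()
    module_genes: list[str] = []
    for m in lhs_mods:
        module_genes.extend(objs[m].members)
    overlap = de.intersect_genes(up, module_genes)
    io.write_table(pd.DataFrame({"gene": overlap}),
                   Path("results") / "overlap_genes.tsv")
    truth = json.loads((DATA / "ground_truth.json").read_text())
    n_sig = len(set(overlap) & set(truth["signature_genes"]))
    print(f"{len(overlap)} up-DEGs overlap LHS modules "
          f"({n_sig} of the planted signature)")


if __name__ == "__main__":
    main()
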