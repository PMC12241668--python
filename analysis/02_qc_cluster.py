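#!/usr/bin/env python
"""QC, normalization, HVG selection, PCA and Leiden clustering.

Reads results/data/, writes results/qc/: the QC report, the PCA embedding,
cluster labels and per-cluster marker genes (Wilcoxon, p<0.01, log2FC>0.25).
"""

from pathlib import Path

from lactoscore import io, qc

DATA = Path("results/data")
OUT = Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts_triplet(
        DATA / "matrix.mtx", DATA / "genes.tsv", DATA / "barcodes.tsv"
    )
    filtered, report = qc.apply_qc(counts)
    io.write_table(report.to_frame(), OUT / "qc_report.tsv")
    print(f"QC: {report.n_cells_in} -> {report.n_cells_out} cells, "
          f"{report.n_genes_in} -> {report.n_genes_out} genes")

    norm = qc.lognormalize(filtered)
    hvgs = qc.select_hvgs(norm, qc.HvgPcaParams().n_hvgs)
    emb = qc.run_pca(norm, hvgs, qc.HvgPcaParams().n_pcs)
    emb.rename_axis("cell_id").reset_index().pipe(
        io.write_table, OUT / "pca_embedding.tsv"
    )

    clusters = qc.cluster_cells(emb, resolution=0.8, seed=0)
    clusters.rename_axis("cell_id").reset_index(name="cluster").pipe(
        io.write_table, OUT / "clusters.tsv"
    )
    print(f"{len(hvgs)} HVGs, {emb.shape[1]} PCs, "
          f"{clusters.nunique()} Leiden clusters at resolution 0.8")

    markers = qc.find_markers(norm, clusters)
    io.write_table(markers, OUT / "cluster_markers.tsv")
    per = markers.groupby("group").size()
    print("positive markers per cluster:", dict(per))


if __name__ == "__main__":
    main()
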