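#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/data/:
  matrix.mtx / genes.tsv / barcodes.tsv  -- single-cell counts (10x layout)
  signature.gmt                          -- the planted lactylation signature
  ground_truth.json                      -- planted cells/genes for later checks
  spatial_* / spatial_coords.tsv         -- spot grid with a planted region

Conditions: 2000 cells x 3000 genes, a 50-gene signature over-expressed
4-fold in a planted 25% of cells, 4 cell types, NB dispersion 0.5.
"""

import json
from pathlib import Path

from lactoscore import io, synth

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.SimulationConfig(seed=SEED)

    counts, truth = synth.simulate_sc_counts(cfg)
    io.write_counts_triplet(
        counts, OUT / "matrix.mtx", OUT / "genes.tsv", OUT / "barcodes.tsv"
    )
    io.write_gmt(
        io.GeneSetCollection(
            [io.GeneSet("lactylation_signature",
                        sorted(truth.signature_genes),
                        "planted synthetic signature")]
        ),
        OUT / "signature.gmt",
    )

    spatial, sp_truth = synth.simulate_spatial(
        synth.SimulationConfig(n_cells=900, n_genes=1000,
                               lactylation_set_size=50, seed=SEED)
    )
    io.write_counts_triplet(
        spatial.counts, OUT / "spatial_matrix.mtx",
        OUT / "spatial_genes.tsv", OUT / "spatial_barcodes.tsv",
    )
    io.write_table(spatial.coords, OUT / "spatial_coords.tsv")

    (OUT / "ground_truth.json").write_text(json.dumps({
        "planted_high_cells": sorted(truth.planted_high_cells),
        "signature_genes": sorted(truth.signature_genes),
        "planted_region_spots": sorted(sp_truth.planted_region_spots),
        "seed": SEED,
    }, indent=2))

    print(f"single-cell counts: {counts.n_cells} cells x {counts.n_genes} genes")
    print(f"planted high-activity cells: {len(truth.planted_high_cells)}")
    print(f"signature size: {len(truth.signature_genes)}")
    print(f"spatial spots: {spatial.counts.n_cells} "
          f"(planted region {len(sp_truth.planted_region_spots)})")


if __name__ == "__main__":
    main()
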