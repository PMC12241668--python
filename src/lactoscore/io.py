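"""Readers and writers for the external formats the pipeline touches.

The on-disk formats are deliberately plain: Matrix Market triplets with
one-per-line gene/barcode sidecars for count matrices (the 10x-style layout),
GMT for gene sets, and TSV for every report the pipeline emits.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_counts_triplet",
    "write_counts_triplet",
    "read_counts_dense",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class CountMatrix:
    """Cells x genes expression matrix with identifiers.

    ``values`` is a sparse CSR matrix, rows are cells. ``layer_tag`` records
    whether the matrix holds raw counts ("counts") or log-normalized
    expression ("lognorm").
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.layer_tag not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "counts":
            d = self.values.data
            if d.size and (np.any(d < 0) or np.any(d != np.round(d))):
                raise ValueError("counts layer must hold non-negative integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Column indices of ``genes`` present in the matrix (order kept)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return replace(self, values=self.values[mask], cell_ids=self.cell_ids[mask])

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return replace(
            self, values=self.values[:, mask], gene_ids=self.gene_ids[mask]
        )


@dataclass
class GeneSet:
    """A named, ordered, duplicate-free gene list."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        deduped = list(dict.fromkeys(self.genes))
        if len(deduped) != len(self.genes):
            warnings.warn(
                f"gene set {self.name!r}: dropped "
                f"{len(self.genes) - len(deduped)} duplicate member(s)"
            )
            self.genes = deduped

    def __len__(self) -> int:
        return len(self.genes)

    def matched_fraction(self, gene_ids: Sequence[str]) -> float:
        """Fraction of members present in ``gene_ids`` (exact, case-sensitive)."""
        universe = set(gene_ids)
        return sum(g in universe for g in self.genes) / len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_counts_triplet(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Load a sparse count matrix in Matrix Market + sidecar layout.

    On-disk orientation (cells x genes vs the 10x genes x cells convention)
    is auto-detected by matching matrix dimensions against the lengths of the
    id files; a square matrix with equal id counts is ambiguous and rejected.
    """
    mat = sp.coo_matrix(scipy.io.mmread(str(matrix_path)))
    genes = _read_lines(genes_path)
    # 10x genes.tsv may carry ensembl_id<TAB>symbol; keep the last column
    genes = [g.split("\t")[-1] for g in genes]
    barcodes = _read_lines(barcodes_path)
    n_rows, n_cols = mat.shape
    if (n_rows, n_cols) == (len(barcodes), len(genes)):
        if n_rows == n_cols and len(genes) == len(barcodes):
            raise ValueError(
                "square matrix with equal gene/barcode counts: "
                "orientation is ambiguous"
            )
        oriented = mat
    elif (n_rows, n_cols) == (len(genes), len(barcodes)):
        oriented = mat.T
    else:
        raise ValueError(
            f"matrix is {n_rows}x{n_cols} but sidecars list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    values = sp.csr_matrix(oriented)
    if values.size and np.all(values.data == np.round(values.data)):
        values = values.astype(np.int64)
    return CountMatrix(values=values, cell_ids=barcodes, gene_ids=genes)


def write_counts_triplet(
    cm: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the 10x-style genes x cells Matrix Market layout."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.values.T))
    Path(genes_path).write_text("".join(f"{g}\n" for g in cm.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in cm.cell_ids))


def read_counts_dense(path: str | Path, layer_tag: str = "counts") -> CountMatrix:
    """Read a dense TSV with gene columns and a cell-id index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = sp.csr_matrix(df.to_numpy())
    if layer_tag == "counts":
        values = values.astype(np.int64)
    return CountMatrix(
        values=values,
        cell_ids=df.index.astype(str).to_numpy(),
        gene_ids=df.columns.astype(str).to_numpy(),
        layer_tag=layer_tag,
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file: name, description, members..."""
    sets: list[GeneSet] = []
    lines = _read_lines(path)
    if not lines:
        raise ValueError(f"GMT file {path} is empty")
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            warnings.warn(f"GMT line {i}: fewer than 3 fields, skipped")
            continue
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    if not sets:
        raise ValueError(f"GMT file {path} contains no valid gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a report as UTF-8 TSV with header and '.' decimal separator."""
    path = Path(path)
    try:
        records.to_csv(path, sep="\t", index=False, encoding="utf-8")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
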