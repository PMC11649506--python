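"""Core data containers and 10x-style triplet I/O.

A :class:`CountMatrix` holds named sparse integer layers (spliced, unspliced,
ambiguous, total) over a fixed gene x barcode grid.  Internally layers are CSR
with cells as rows (every downstream operation is per-cell); on disk the
MatrixMarket convention is genes x cells, matching CellRanger/alevin-fry
output, and the readers/writers transpose accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

LAYER_NAMES = ("spliced", "unspliced", "ambiguous", "total")

__all__ = ["CountMatrix", "read_10x_triplet", "write_10x_triplet"]


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts with named layers.

    Parameters
    ----------
    gene_ids
        Ordered gene identifiers (length G).
    barcodes
        Ordered cell barcodes (length C).
    layers
        Mapping layer name -> ``csr_matrix`` of shape (C, G).  If the three
        component layers are present but ``total`` is not, it is derived as
        their elementwise sum.
    provenance
        Free-form history: source paths and applied filters.
    """

    gene_ids: np.ndarray
    barcodes: np.ndarray
    layers: dict[str, sp.csr_matrix]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not self.layers:
            raise ValueError("at least one layer required")
        components = [n for n in ("spliced", "unspliced", "ambiguous") if n in self.layers]
        if "total" not in self.layers and len(components) == 3:
            self.layers["total"] = sum(self.layers[n] for n in components).tocsr()
        shape = (len(self.barcodes), len(self.gene_ids))
        for name, mat in self.layers.items():
            mat = sp.csr_matrix(mat)
            if mat.shape != shape:
                raise ValueError(f"layer {name!r} has shape {mat.shape}, expected {shape}")
            if mat.nnz and mat.data.min() < 0:
                raise ValueError(f"layer {name!r} contains negative entries")
            self.layers[name] = mat

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def layer(self, name: str = "total") -> sp.csr_matrix:
        return self.layers[name]

    def total_counts(self, layer: str = "total") -> np.ndarray:
        """Per-barcode library size for the given layer."""
        return np.asarray(self.layer(layer).sum(axis=1)).ravel()

    def subset_cells(self, mask_or_index, note: str | None = None) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        layers = {k: v[idx].tocsr() for k, v in self.layers.items()}
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return CountMatrix(self.gene_ids, self.barcodes[idx], layers, prov)

    def subset_genes(self, mask_or_index, note: str | None = None) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        layers = {k: v[:, idx].tocsr() for k, v in self.layers.items()}
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return CountMatrix(self.gene_ids[idx], self.barcodes, layers, prov)

    def layers_consistent(self) -> bool:
        """True when spliced+unspliced+ambiguous equals total exactly."""
        needed = {"spliced", "unspliced", "ambiguous", "total"}
        if not needed <= set(self.layers):
            return True
        s = self.layers["spliced"] + self.layers["unspliced"] + self.layers["ambiguous"]
        return (s != self.layers["total"]).nnz == 0


def write_10x_triplet(m: CountMatrix, outdir: str | Path, layer: str = "total") -> Path:
    """Write one layer as a 10x-style triplet (matrix.mtx genes x cells,
    features.tsv, barcodes.tsv).  Extra layers go to ``<name>.mtx``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m.layer(layer).T.tocoo())
    for name, mat in m.layers.items():
        if name != layer:
            scipy.io.mmwrite(str(outdir / f"{name}.mtx"), mat.T.tocoo())
    feats = pd.DataFrame(
        {"id": m.gene_ids, "symbol": m.gene_ids, "type": "Gene Expression"}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    return outdir


def read_10x_triplet(indir: str | Path) -> CountMatrix:
    """Read a triplet directory written by :func:`write_10x_triplet` (or any
    genes x cells MatrixMarket triplet with features/barcodes TSVs)."""
    indir = Path(indir)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    layers: dict[str, sp.csr_matrix] = {}
    main = scipy.io.mmread(str(indir / "matrix.mtx"))
    layers["total"] = sp.csr_matrix(main.T)
    for name in ("spliced", "unspliced", "ambiguous"):
        p = indir / f"{name}.mtx"
        if p.exists():
            layers[name] = sp.csr_matrix(scipy.io.mmread(str(p)).T)
    return CountMatrix(
        feats[0].to_numpy(), barcodes, layers, provenance=[f"read_10x_triplet:{indir}"]
    )
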