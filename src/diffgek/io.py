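"""Reading and writing dataset bundles.

A run needs three things: a spliced and an unspliced gene-by-cell count
matrix (normalized/imputed upstream, e.g. by the standard scVelo moments
step) and a cell-metadata table with pseudotime, condition label, hard
lineage assignment and optionally a replicate/sample label.  Two on-disk
layouts are supported, matching the velocyto/scVelo ecosystem:

* a directory with ``spliced.mtx``, ``unspliced.mtx`` (genes x cells),
  ``genes.tsv``, ``barcodes.tsv`` and ``cell_meta.tsv``;
* an ``.h5ad`` file with ``spliced``/``unspliced`` layers and the metadata
  columns in ``.obs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["DatasetBundle", "read_mtx_bundle", "write_mtx_bundle", "read_h5ad", "from_anndata"]

REQUIRED_META = ("pseudotime", "condition", "lineage")


@dataclass
class DatasetBundle:
    """In-memory dataset: two gene-by-cell layers plus cell metadata.

    ``cell_meta`` is indexed by barcode and must provide ``pseudotime``
    (float), ``condition`` (label), ``lineage`` (truthy = hard-assigned to
    the analysed lineage) and optionally ``sample``.  ``gene_list``
    restricts the analysis (at most ~2000 highly variable genes are
    recommended upstream).
    """

    spliced: np.ndarray | sp.spmatrix
    unspliced: np.ndarray | sp.spmatrix
    genes: pd.Index
    cells: pd.Index
    cell_meta: pd.DataFrame
    gene_list: list[str] | None = None
    layer_name: str = "imputed"

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        for name, mat in (("spliced", self.spliced), ("unspliced", self.unspliced)):
            if mat.shape != (self.genes.size, self.cells.size):
                raise ValueError(
                    f"{name} matrix shape {mat.shape} does not match "
                    f"{self.genes.size} genes x {self.cells.size} cells"
                )
        missing = [c for c in REQUIRED_META if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta is missing required columns: {missing}")
        if not self.cell_meta.index.equals(self.cells):
            if set(self.cell_meta.index) != set(self.cells):
                raise ValueError("cell_meta index does not match the cell barcodes")
            self.cell_meta = self.cell_meta.loc[self.cells]
        lineage = self.lineage_mask
        pt = pd.to_numeric(self.cell_meta["pseudotime"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(pt[lineage])):
            raise ValueError("pseudotime must be finite for all lineage-assigned cells")

    @property
    def lineage_mask(self) -> np.ndarray:
        return self.cell_meta["lineage"].astype(bool).to_numpy()

    @property
    def conditions(self) -> tuple[str, ...]:
        labels = self.cell_meta.loc[self.lineage_mask, "condition"].astype(str)
        return tuple(pd.unique(labels))

    def gene_index(self, gene: str) -> int:
        try:
            return int(self.genes.get_loc(gene))
        except KeyError:
            raise KeyError(f"gene '{gene}' not present in the bundle") from None

    def gene_vectors(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense (unspliced, spliced) per-cell vectors of one gene."""
        gi = self.gene_index(gene)
        u = self.unspliced[gi]
        s = self.spliced[gi]
        if sp.issparse(u):
            u = np.asarray(u.todense()).ravel()
            s = np.asarray(s.todense()).ravel()
        return np.asarray(u, float).ravel(), np.asarray(s, float).ravel()

    def analysis_genes(self) -> list[str]:
        if self.gene_list is not None:
            missing = [g for g in self.gene_list if g not in self.genes]
            if missing:
                raise KeyError(f"gene_list entries absent from the bundle: {missing[:5]}")
            return list(self.gene_list)
        return list(self.genes)


def write_mtx_bundle(bundle: DatasetBundle, directory) -> None:
    """Write a bundle as MTX + TSV files (genes x cells orientation)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, mat in (("spliced", bundle.spliced), ("unspliced", bundle.unspliced)):
        mmwrite(str(d / f"{name}.mtx"), sp.coo_matrix(mat))
    pd.Series(bundle.genes).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(bundle.cells).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    bundle.cell_meta.to_csv(d / "cell_meta.tsv", sep="\t", index_label="barcode")
    if bundle.gene_list is not None:
        pd.Series(bundle.gene_list).to_csv(
            d / "gene_list.tsv", sep="\t", index=False, header=False
        )


def read_mtx_bundle(directory) -> DatasetBundle:
    """Read a bundle written by :func:`write_mtx_bundle` (or velocyto-style)."""
    d = Path(directory)
    spliced = sp.csr_matrix(mmread(str(d / "spliced.mtx")))
    unspliced = sp.csr_matrix(mmread(str(d / "unspliced.mtx")))
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    meta = pd.read_csv(d / "cell_meta.tsv", sep="\t", index_col="barcode")
    gene_list = None
    gl = d / "gene_list.tsv"
    if gl.exists():
        gene_list = pd.read_csv(gl, sep="\t", header=None)[0].tolist()
    return DatasetBundle(
        spliced=spliced,
        unspliced=unspliced,
        genes=pd.Index(genes.astype(str)),
        cells=pd.Index(cells.astype(str)),
        cell_meta=meta,
        gene_list=gene_list,
    )


def from_anndata(adata, spliced_layer="spliced", unspliced_layer="unspliced") -> DatasetBundle:
    """Bundle from an AnnData with spliced/unspliced layers and obs metadata."""
    for layer in (spliced_layer, unspliced_layer):
        if layer not in adata.layers:
            raise ValueError(f"AnnData has no layer '{layer}'")
    meta_cols = [c for c in adata.obs.columns if c in REQUIRED_META + ("sample",)]
    meta = adata.obs[meta_cols].copy()
    return DatasetBundle(
        spliced=sp.csr_matrix(adata.layers[spliced_layer].T),
        unspliced=sp.csr_matrix(adata.layers[unspliced_layer].T),
        genes=pd.Index(adata.var_names.astype(str)),
        cells=pd.Index(adata.obs_names.astype(str)),
        cell_meta=meta,
        layer_name=spliced_layer,
    )


def read_h5ad(path, **kwargs) -> DatasetBundle:
    import anndata

    return from_anndata(anndata.read_h5ad(path), **kwargs)
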