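"""Shared in-memory containers: expression matrices with layers."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


class ExpressionMatrix:
    """Genes x samples abundance matrix with named layers.

    Layers (e.g. ``"total"`` and the derived ``"new"``) are pandas
    DataFrames sharing one gene index and one sample column axis.
    """

    def __init__(self, layers: Mapping[str, pd.DataFrame]):
        if not layers:
            raise ValueError("at least one layer is required")
        layers = {name: df.copy() for name, df in layers.items()}
        first = next(iter(layers.values()))
        for name, df in layers.items():
            if not df.index.equals(first.index) or not df.columns.equals(first.columns):
                raise ValueError(f"layer {name!r} axes do not match")
        self.layers: dict[str, pd.DataFrame] = dict(layers)

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.layers.values())).index

    @property
    def samples(self) -> pd.Index:
        return next(iter(self.layers.values())).columns

    def __getitem__(self, layer: str) -> pd.DataFrame:
        return self.layers[layer]

    def __contains__(self, layer: str) -> bool:
        return layer in self.layers

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.layers)

    # --- persistence -------------------------------------------------
    def to_tsv(self, path: str | Path, layer: str = "total") -> None:
        self.layers[layer].to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, layer: str = "total") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
        return cls({layer: df})

    def to_mtx(self, path_prefix: str | Path, layer: str = "total") -> None:
        """Write Matrix Market triple: <prefix>.mtx, <prefix>.genes.tsv,
        <prefix>.samples.tsv."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        prefix = Path(path_prefix)
        df = self.layers[layer]
        mmwrite(str(prefix) + ".mtx", csr_matrix(df.to_numpy()))
        pd.Series(df.index).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)
        pd.Series(df.columns).to_csv(str(prefix) + ".samples.tsv", sep="\t", index=False, header=False)

    @classmethod
    def from_mtx(cls, path_prefix: str | Path, layer: str = "total") -> "ExpressionMatrix":
        from scipy.io import mmread

        prefix = str(Path(path_prefix))
        mat = mmread(prefix + ".mtx").toarray()
        genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0]
        samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", header=None)[0]
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=list(samples))
        return cls({layer: df})
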