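"""Samples x variables container shared by both analytical blocks.

A :class:`FeatureTable` carries the numeric matrix, a block tag per variable
("NMR" or "MS"), and per-sample metadata (the response candidates: diet,
time-on-diet, diabetes status, clinical covariates). Fusion is plain
column-wise concatenation of independently z-scored blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "zscore", "fuse_blocks"]


@dataclass
class FeatureTable:
    data: pd.DataFrame  # samples x variables
    blocks: pd.Series  # variable -> "NMR" | "MS"
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.metadata is None or len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=self.data.index)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate variable ids")
        if not self.blocks.index.equals(self.data.columns):
            self.blocks = self.blocks.reindex(self.data.columns)
        if self.blocks.isna().any():
            raise ValueError("every variable needs a block tag")
        if not self.metadata.index.equals(self.data.index):
            self.metadata = self.metadata.reindex(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def subset_block(self, block: str) -> "FeatureTable":
        cols = self.blocks.index[self.blocks == block]
        return FeatureTable(self.data[cols], self.blocks[cols], self.metadata)

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)

    def with_metadata(self, metadata: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(self.data, self.blocks, metadata.reindex(self.data.index))


def zscore(table: FeatureTable) -> FeatureTable:
    """Standardize each variable to mean 0, sample SD 1 (ddof=1).

    Zero-variance variables are dropped with a warning; an all-constant table
    raises.
    """
    sd = table.data.std(ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variables are constant; nothing to standardize")
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} zero-variance variable(s) before z-scoring",
            stacklevel=2,
        )
    data = table.data.loc[:, keep]
    z = (data - data.mean()) / data.std(ddof=1)
    return FeatureTable(z, table.blocks[keep.index[keep]], table.metadata)


def fuse_blocks(nmr: FeatureTable, ms: FeatureTable) -> FeatureTable:
    """Concatenate two blocks column-wise over the shared sample set.

    Samples are matched by id (order may differ); output sample order follows
    the NMR table. A sample-set mismatch raises with the asymmetric
    difference spelled out.
    """
    a, b = set(nmr.data.index), set(ms.data.index)
    if a != b:
        raise ValueError(
            f"sample sets differ: only in first block {sorted(a - b)}, "
            f"only in second {sorted(b - a)}"
        )
    ms_data = ms.data.reindex(nmr.data.index)
    data = pd.concat([nmr.data, ms_data], axis=1)
    blocks = pd.concat([nmr.blocks, ms.blocks])
    meta = nmr.metadata if nmr.metadata.shape[1] else ms.metadata.reindex(nmr.data.index)
    return FeatureTable(data, blocks, meta)
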