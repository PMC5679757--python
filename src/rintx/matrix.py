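"""Expression matrix container.

A thin wrapper around a genes x samples DataFrame carrying an explicit
scale flag, so that operations that assume linear FPKM (TbT scaling) or
log2(FPKM + 1) (RIN correction, differential expression) can assert the
space they require instead of silently mixing scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LINEAR = "linear_fpkm"
LOG2 = "log2_fpkm_plus1"


@dataclass
class ExpressionMatrix:
    data: pd.DataFrame  # genes x samples
    space: str = LINEAR

    def __post_init__(self) -> None:
        if self.space not in (LINEAR, LOG2):
            raise ValueError(f"unknown space: {self.space!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if self.space == LINEAR and vals.size and vals.min() < 0:
            raise ValueError("linear FPKM values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self) -> "ExpressionMatrix":
        if self.space == LOG2:
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), space=LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        if self.space == LINEAR:
            return self
        linear = (2.0 ** self.data - 1.0).clip(lower=0.0)
        return ExpressionMatrix(linear, space=LINEAR)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], space=self.space)

    def total_log2_signal(self) -> float:
        """Sum of log2(FPKM + 1) over the whole matrix."""
        return float(self.to_log2().data.to_numpy().sum())
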