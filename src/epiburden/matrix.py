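"""Methylation matrix container and TSV round-tripping.

The central in-memory object of the pipeline is a probes x samples grid of
methylation values carried either on the beta scale (fraction methylated,
open interval (0, 1)) or on the M scale (log2 odds of methylation).  The
scale is tracked explicitly so downstream steps can refuse input on the
wrong scale instead of silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BETA_SCALE = "beta"
M_SCALE = "M"


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong value scale."""


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one column per sample ID.
        Missing values are explicit NaN.
    scale
        Either ``"beta"`` (values in the open unit interval) or ``"M"``
        (log2 odds, unbounded).
    """

    values: pd.DataFrame
    scale: str = BETA_SCALE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in (BETA_SCALE, M_SCALE):
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe IDs in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in matrix")
        if self.scale == BETA_SCALE:
            arr = self.values.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and ((finite <= 0).any() or (finite >= 1).any()):
                raise ValueError("beta-scale values must lie strictly in (0, 1)")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.values.copy(), self.scale, dict(self.meta))

    def to_tsv(self, path) -> None:
        """Write as TSV: first column the probe ID, one column per sample."""
        out = self.values.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scale: str = BETA_SCALE) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, scale=scale)
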