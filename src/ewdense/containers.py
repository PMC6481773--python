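"""In-memory containers shared across pipeline stages.

The background protein–protein interaction network is a plain
:class:`networkx.Graph` whose nodes are upper-case gene symbols; the
containers here wrap the tabular inputs (GWAS summary statistics, expression
panels, probe-level S-scores) with their minimal validity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GwasGeneStats", "ExpressionPanel", "SScorePanel"]


@dataclass(frozen=True)
class GwasGeneStats:
    """Gene-level association p-values for one GWAS.

    ``p`` is indexed by unique gene symbol; values must lie in (0, 1].
    """

    study: str
    p: pd.Series = field(repr=False)

    def __post_init__(self):
        if self.p.empty:
            raise ValueError(f"{self.study}: empty GWAS table")
        if self.p.index.has_duplicates:
            dup = self.p.index[self.p.index.duplicated()][0]
            raise ValueError(f"{self.study}: duplicate gene symbol {dup!r}")
        vals = self.p.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any() or (vals > 1).any():
            raise ValueError(f"{self.study}: p-values must lie in (0, 1]")

    @property
    def genes(self) -> set[str]:
        return set(self.p.index)


@dataclass(frozen=True)
class ExpressionPanel:
    """Genes x strains expression matrix for one region and condition.

    Values are on the RMA scale (log2-like, background corrected).
    """

    region: str
    condition: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.condition not in ("control", "treatment"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene rows in expression panel")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)

    @property
    def n_strains(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SScorePanel:
    """Probeset x strain S-scores for one region.

    S-scores contrast treated vs. control arrays at the probe level and are
    approximately standard normal under the no-response null, which is what
    the downstream Fisher combination relies on.
    """

    region: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probeset rows in S-score panel")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite S-scores")

    @property
    def probesets(self) -> list[str]:
        return list(self.values.index)
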