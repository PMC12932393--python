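"""Shared data containers for methylation matrices and pseudobulk expression."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta values with probe annotation.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns;
    every entry lies strictly in (0, 1).  ``probe_coords`` carries chromosome
    and 0-based half-open position per probe; ``platform_tags`` marks array
    membership (e.g. "EPIC", "450K").
    """

    values: pd.DataFrame
    probe_coords: pd.DataFrame  # columns: chrom, pos
    platform_tags: pd.Series

    def __post_init__(self):
        v = self.values.to_numpy()
        if not np.all((v > 0) & (v < 1)):
            raise ValueError("beta values must lie strictly in (0, 1)")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ResidualMatrix:
    """Probes x samples residuals after covariate regression.

    ``design_columns`` names the covariates (including the intercept) that
    were regressed out; per-probe residuals are orthogonal to each of them.
    """

    values: pd.DataFrame
    design_columns: list[str] = field(default_factory=list)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class StatePseudobulk:
    """Summed expression of one microglial state: genes x samples.

    ``cell_counts`` gives the number of cells aggregated per sample and
    ``groups`` the diagnostic group of each sample; ``marker_genes`` is the
    state's marker set (a subset of the gene index).
    """

    state: str
    counts: pd.DataFrame
    cell_counts: pd.Series
    groups: pd.Series
    marker_genes: list[str]

    def __post_init__(self):
        if not set(self.marker_genes) <= set(self.counts.index):
            raise ValueError("marker genes must be a subset of the gene index")
        if (self.cell_counts < 0).any():
            raise ValueError("cell counts must be non-negative")
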