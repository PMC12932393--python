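"""Set-overlap and genomic-feature enrichment statistics.

Overlap between CpG (or gene) sets is summarized by the classical
Fisher-test pairing: a one-sided hypergeometric enrichment p-value and the
conditional maximum-likelihood estimate of the noncentral hypergeometric
odds ratio (the value R's fisher.test and GeneOverlap report, slightly
below the sample odds ratio).  Regulatory-interval enrichment maps CpGs
into half-open BED intervals; cell-type panel enrichment tests
specificity-stratified CpG reference panels.  BH correction is applied
within each feature/panel family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import contingency, hypergeom

from ._utils import bh_adjust


@dataclass
class OverlapTable:
    both: int          # |A n B|
    a_only: int        # |A \ B|
    b_only: int        # |B \ A|
    neither: int       # |U \ (A u B)|

    @property
    def universe(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.both, self.a_only], [self.b_only, self.neither]])


def overlap_table_from_counts(overlap: int, size_a: int, size_b: int,
                              universe: int) -> OverlapTable:
    if overlap > min(size_a, size_b) or size_a + size_b - overlap > universe:
        raise ValueError("inconsistent overlap counts")
    return OverlapTable(both=overlap, a_only=size_a - overlap,
                        b_only=size_b - overlap,
                        neither=universe - size_a - size_b + overlap)


def fisher_from_table(table: OverlapTable, alternative: str = "greater"):
    """Conditional-MLE odds ratio + hypergeometric enrichment p for a table."""
    if (table.both + table.a_only == 0) or (table.both + table.b_only == 0):
        return np.nan, 1.0
    size_a = table.both + table.a_only
    size_b = table.both + table.b_only
    if alternative == "greater":
        p = float(hypergeom.sf(table.both - 1, table.universe, size_a, size_b))
    elif alternative == "two-sided":
        from scipy.stats import fisher_exact
        p = float(fisher_exact(table.as_array(), alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    orr = contingency.odds_ratio(table.as_array(), kind="conditional")
    return float(orr.statistic), p


def fisher_overlap(set_a, set_b, universe, alternative: str = "greater"):
    """Overlap of two sets within a universe.

    Returns (odds_ratio, p, OverlapTable).  The odds ratio is the
    conditional MLE; p is the one-sided upper-tail hypergeometric
    (enrichment) probability unless ``alternative='two-sided'``.
    """
    U = set(universe)
    A, B = set(set_a), set(set_b)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    table = overlap_table_from_counts(len(A & B), len(A), len(B), len(U))
    orr, p = fisher_from_table(table, alternative)
    return orr, p, table


def _interval_members(coords: pd.DataFrame, intervals: pd.DataFrame) -> pd.Index:
    """CpGs whose position falls in any half-open [start, end) interval."""
    if (intervals["start"] >= intervals["end"]).any():
        bad = intervals[intervals["start"] >= intervals["end"]]
        raise ValueError(f"malformed intervals (start >= end):\n{bad}")
    hits = []
    for chrom, sub in intervals.groupby("chrom"):
        cpgs = coords[coords["chrom"] == chrom]
        if cpgs.empty:
            continue
        pos = cpgs["pos"].to_numpy()
        inside = np.zeros(len(pos), dtype=bool)
        for start, end in sub[["start", "end"]].itertuples(index=False):
            inside |= (pos >= start) & (pos < end)
        hits.append(cpgs.index[inside])
    return hits[0].append(hits[1:]) if hits else pd.Index([])


def regulatory_enrichment(cpg_sets: dict[str, set],
                          peak_intervals: dict[str, pd.DataFrame],
                          universe_coords: pd.DataFrame) -> pd.DataFrame:
    """Enrichment of subtype CpG sets in regulatory features.

    ``peak_intervals`` maps feature name -> DataFrame(chrom, start, end) in
    0-based half-open convention; ``universe_coords`` is indexed by CpG id
    with chrom/pos columns.  Fisher tests per feature vs the background
    universe, BH-corrected across features within each subtype set.
    """
    universe = set(universe_coords.index)
    members = {feat: set(_interval_members(universe_coords, iv))
               for feat, iv in peak_intervals.items()}
    rows = []
    for subtype, cpgs in cpg_sets.items():
        subset = []
        for feat, inside in members.items():
            orr, p, table = fisher_overlap(set(cpgs) & universe, inside, universe)
            subset.append({"set": subtype, "feature": feat, "odds_ratio": orr,
                           "p": p, "overlap": table.both,
                           "proportion": table.both / max(len(cpgs), 1)})
        sub = pd.DataFrame(subset)
        sub["q"] = bh_adjust(sub["p"].to_numpy())
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def celltype_enrichment(dmps, panels: pd.DataFrame, universe) -> pd.DataFrame:
    """Enrichment of DMPs in cell-type CpG panels by specificity level.

    ``panels`` has columns cpg_id, cell_type, level; one Fisher test per
    (cell type, level), BH within the panel family.
    """
    universe = set(universe)
    dmps = set(dmps) & universe
    rows = []
    for (cell, level), sub in panels.groupby(["cell_type", "level"]):
        panel = set(sub["cpg_id"]) & universe
        orr, p, table = fisher_overlap(dmps, panel, universe)
        rows.append({"cell_type": cell, "level": level, "odds_ratio": orr,
                     "p": p, "overlap": table.both, "panel_size": len(panel)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
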