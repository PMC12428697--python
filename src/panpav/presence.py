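"""Gene presence calling from coverage breadth.

A gene is called present in a sample when both its gene-body breadth and
its CDS breadth (fractions of positions covered at >= ``min_depth``) meet
their thresholds — the two-parameter rule of map-to-pan PAV callers, with
0.4/0.4 defaults and inclusive boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from panpav.containers import validate_pav

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene's span and CDS intervals, 0-based half-open on one contig."""

    gene: str
    chrom: str
    start: int
    end: int
    cds: Sequence[tuple[int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene span for {self.gene}")
        for s, e in self.cds:
            if not 0 <= s < e:
                raise ValueError(f"invalid CDS interval ({s}, {e}) for {self.gene}")


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _covered_in(
    covered: list[tuple[int, int]], intervals: Sequence[tuple[int, int]]
) -> int:
    """Bases of the interval union that fall inside *covered* (both merged)."""
    total = 0
    for s, e in merge_intervals(intervals):
        for cs, ce in covered:
            total += max(0, min(e, ce) - max(s, cs))
    return total


def breadth_from_depth(
    depth: pd.DataFrame, gene: GeneModel, min_depth: int = 1
) -> dict:
    """Breadth of coverage for one gene from a bedgraph-style depth track.

    *depth* holds columns ``chrom``, ``start``, ``end``, ``depth``
    (0-based half-open, sorted within each contig).  Returns a coverage
    record dict with ``gene_breadth`` over the gene body and
    ``cds_breadth`` over the union of CDS intervals; a gene whose CDS
    union is empty gets ``cds_breadth = NaN`` (explicitly undefined, never
    silently 0).
    """
    track = depth[(depth["chrom"] == gene.chrom) & (depth["depth"] >= min_depth)]
    covered = merge_intervals(list(zip(track["start"], track["end"])))

    gene_len = gene.end - gene.start
    gene_cov = _covered_in(covered, [(gene.start, gene.end)])

    cds_union = merge_intervals(gene.cds)
    cds_len = sum(e - s for s, e in cds_union)
    cds_breadth = _covered_in(covered, cds_union) / cds_len if cds_len else np.nan

    return {
        "gene": gene.gene,
        "gene_breadth": gene_cov / gene_len,
        "cds_breadth": cds_breadth,
    }


def call_presence(
    coverage: pd.DataFrame, t_gene: float = 0.4, t_cds: float = 0.4
) -> pd.DataFrame:
    """Call the binary PAV matrix from a long coverage table.

    Present (1) iff ``gene_breadth >= t_gene`` AND ``cds_breadth >= t_cds``
    (both boundaries inclusive, so breadths equal to the printed 0.4
    parameters pass).  Requires exactly one record per (gene, sample);
    genes with an undefined CDS breadth in any sample are excluded from
    the matrix with a logged reason.
    """
    for t, name in ((t_gene, "t_gene"), (t_cds, "t_cds")):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    dup = coverage.duplicated(subset=["gene", "sample"])
    if dup.any():
        offenders = coverage.loc[dup, ["gene", "sample"]].to_records(index=False)
        raise ValueError(f"duplicate coverage records: {list(offenders)[:10]}")

    wide_gene = coverage.pivot(index="gene", columns="sample", values="gene_breadth")
    wide_cds = coverage.pivot(index="gene", columns="sample", values="cds_breadth")
    missing_pairs = wide_gene.isna()
    if missing_pairs.to_numpy().any():
        offenders = [
            (g, s)
            for g, row in missing_pairs.iterrows()
            for s in row.index[row]
        ]
        raise ValueError(f"missing coverage records for: {offenders[:10]}")

    undefined = wide_cds.isna().any(axis=1)
    if undefined.any():
        for g in wide_cds.index[undefined]:
            logger.warning("gene %s excluded: CDS breadth undefined", g)
        wide_gene = wide_gene[~undefined]
        wide_cds = wide_cds[~undefined]

    pav = ((wide_gene >= t_gene) & (wide_cds >= t_cds)).astype(np.int8)
    pav.index.name = "gene"
    pav.columns.name = None
    return validate_pav(pav)
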