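"""Non-reference contig filtering and repeat-proportion summaries.

Contigs assembled from reads that failed to map to the reference are kept
only when longer than 500 bp (strict) and covered by reference alignments
over less than 80% (strict) of their length, with alignment intervals
merged on the contig before the overlap rate is computed.  Contigs
classified as organellar or non-plant by an upstream similarity search are
then removed.  Repeat-masking results are summarised as percentages of the
total non-reference length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from panpav.pangenome import pct
from panpav.presence import merge_intervals

ORGANELLE_CLASSES = frozenset({"mitochondrion", "chloroplast"})
CONTAMINANT_CLASSES = frozenset({"non_plant"})


@dataclass
class FilterReport:
    """Kept and removed contigs with exclusive per-rule removal reasons."""

    kept: list[str]
    removed: pd.DataFrame  # columns: contig, reason
    tallies: dict[str, int]


def contig_filter(
    contigs: pd.DataFrame,
    alignments: pd.DataFrame,
    min_length: int = 500,
    max_overlap: float = 0.80,
) -> FilterReport:
    """Apply the length and reference-overlap rules to assembled contigs.

    *contigs* has columns ``contig`` and ``length``; *alignments* carries
    query-coordinate records (``query``, ``qstart``, ``qend``, 0-based
    half-open), e.g. from :func:`panpav.io.read_paf`.  A contig's overlap
    rate is its merged aligned bases divided by its length; it is kept iff
    ``length > min_length`` and ``overlap < max_overlap`` (both strict).
    Reasons are exclusive, with ``too_short`` checked first.
    """
    lengths = dict(zip(contigs["contig"], contigs["length"]))
    unknown = set(alignments["query"]) - set(lengths)
    if unknown:
        raise ValueError(f"alignments reference unknown contigs: {sorted(unknown)[:10]}")

    by_query = {
        q: list(zip(sub["qstart"], sub["qend"]))
        for q, sub in alignments.groupby("query")
    }
    kept, removed = [], []
    for contig, length in lengths.items():
        if length <= min_length:
            removed.append({"contig": contig, "reason": "too_short"})
            continue
        covered = sum(e - s for s, e in merge_intervals(by_query.get(contig, [])))
        if covered / length >= max_overlap:
            removed.append({"contig": contig, "reason": "high_overlap"})
            continue
        kept.append(contig)

    removed_df = pd.DataFrame(removed, columns=["contig", "reason"])
    tallies = {
        reason: int((removed_df["reason"] == reason).sum())
        for reason in ("too_short", "high_overlap")
    }
    tallies["kept"] = len(kept)
    return FilterReport(kept, removed_df, tallies)


def remove_classified_contigs(
    kept: list[str],
    hits: Mapping[str, str] | pd.DataFrame,
    drop_classes: frozenset[str] = ORGANELLE_CLASSES | CONTAMINANT_CLASSES,
) -> FilterReport:
    """Drop contigs whose similarity-search class marks them as organellar
    or contaminant; unclassified contigs are kept.

    *hits* maps contig ID to a class label (a two-column DataFrame with
    ``contig`` and ``class`` columns is also accepted).
    """
    if isinstance(hits, pd.DataFrame):
        hits = dict(zip(hits["contig"], hits["class"]))

    out_kept, removed = [], []
    for contig in kept:
        cls = hits.get(contig)
        if cls in drop_classes:
            reason = "organelle" if cls in ORGANELLE_CLASSES else "contaminant"
            removed.append({"contig": contig, "reason": reason})
        else:
            out_kept.append(contig)
    removed_df = pd.DataFrame(removed, columns=["contig", "reason"])
    tallies = {
        reason: int((removed_df["reason"] == reason).sum())
        for reason in ("organelle", "contaminant")
    }
    tallies["kept"] = len(out_kept)
    return FilterReport(out_kept, removed_df, tallies)


def repeat_summary(
    family_lengths: Mapping[str, int], total_length: int
) -> pd.DataFrame:
    """Masked-repeat proportions per family plus the grand total.

    Percentages are of *total_length* (the full non-reference sequence
    length), rounded half-up at two decimals.  Masked lengths may not
    exceed the total.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    masked_total = sum(family_lengths.values())
    if masked_total > total_length:
        raise ValueError("masked lengths exceed the total sequence length")
    rows = [
        {"family": fam, "masked_bp": int(bp), "pct": pct(bp, total_length)}
        for fam, bp in family_lengths.items()
    ]
    rows.append(
        {"family": "total", "masked_bp": masked_total, "pct": pct(masked_total, total_length)}
    )
    return pd.DataFrame(rows, columns=["family", "masked_bp", "pct"])
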