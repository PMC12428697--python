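"""Shared in-memory containers.

Conventions used throughout the package:

* A **PAV matrix** is a :class:`pandas.DataFrame` of 0/1 integers with gene
  IDs as the index and sample IDs as the columns.
* A **coverage table** is a long-format :class:`pandas.DataFrame` with
  columns ``gene``, ``sample``, ``gene_breadth``, ``cds_breadth`` (breadths
  are fractions in [0, 1]; an undefined CDS breadth is ``NaN``).
* Genomic intervals are 0-based half-open unless a format dictates
  otherwise (GFF3 and VCF are converted at the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # missing diploid genotype in dosage encoding


@dataclass
class VariantPanel:
    """Bi-allelic SNP sites with diploid genotypes and a population map.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt`` (comma-joined for multi-allelic records), ``qual``.
    genotypes:
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages
        (0, 1, 2) with :data:`MISSING` for uncalled genotypes.  For
        multi-allelic records the dosage counts any non-reference allele;
        such records only survive until filtering.
    samples:
        Ordered sample IDs (columns of ``genotypes``).
    popmap:
        Mapping sample ID -> population label; may be empty.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    popmap: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, mask_or_index) -> "VariantPanel":
        """Subset sites by a boolean mask or positional index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
        )

    def sample_indices(self, population: str) -> np.ndarray:
        """Positional indices of the samples assigned to *population*."""
        idx = [i for i, s in enumerate(self.samples) if self.popmap.get(s) == population]
        if not idx:
            raise KeyError(f"no samples mapped to population {population!r}")
        return np.asarray(idx)


def validate_pav(pav: pd.DataFrame) -> pd.DataFrame:
    """Check a PAV matrix's invariants; returns the (unchanged) frame."""
    if pav.index.has_duplicates:
        raise ValueError("duplicate gene IDs in PAV matrix")
    if pav.columns.has_duplicates:
        raise ValueError("duplicate sample IDs in PAV matrix")
    vals = pav.to_numpy()
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise ValueError("PAV matrix cells must be 0 or 1")
    return pav
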