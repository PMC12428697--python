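"""Nei–Gojobori (1986) Ka/Ks estimation and the core-vs-flexible contrast.

Synonymous/nonsynonymous site counts use the unweighted NG86 convention
(per codon position, the fraction of the three possible base changes that
are synonymous; changes creating a stop codon count as nonsynonymous and
paths through stop codons are excluded); differences at multi-substitution
codons are averaged over all single-step substitution orderings; pS and pN
are Jukes–Cantor corrected into Ks and Ka.  Class contrasts tally pairs
with Ka/Ks above vs below 1 and test the 2×2 table with Pearson's
chi-squared (no continuity correction).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from panpav.pangenome import pct

logger = logging.getLogger(__name__)

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE_CODONS: list[str] = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free aligned coding pair with a pan-genome class label."""

    pair_id: str
    seq1: str
    seq2: str
    label: str = "core"  # "core" or "flexible"

    def __post_init__(self) -> None:
        s1, s2 = self.seq1.upper(), self.seq2.upper()
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)
        if len(s1) != len(s2):
            raise ValueError(f"{self.pair_id}: sequences differ in length")
        if len(s1) % 3 or not s1:
            raise ValueError(f"{self.pair_id}: length must be a positive multiple of 3")
        for seq in (s1, s2):
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.pair_id}: alphabet must be ACGT")
            for i in range(0, len(seq), 3):
                if GENETIC_CODE[seq[i : i + 3]] == "*":
                    raise ValueError(f"{self.pair_id}: internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]


@dataclass
class KaKsResult:
    pair_id: str
    label: str
    s_sites: float  # mean synonymous sites (S bar)
    n_sites: float  # mean nonsynonymous sites (N bar)
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float  # NaN when saturated (p >= 3/4)
    ka: float
    ratio: float  # Ka/Ks; NaN when Ks is 0 or either rate is undefined
    saturated: bool
    stop_only_paths: bool  # some codon had no stop-free substitution path


def _syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (changes to stops are nonsyn)."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:  # stops never match a sense aa
                syn += 1
    return syn / 3.0


def _codon_differences(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathwise-averaged (synonymous, nonsynonymous) differences for one codon.

    Averages over all orderings of the differing positions; orderings that
    pass through a stop codon are excluded.  If every ordering hits a stop,
    all orderings are used (steps to/from stops counted nonsynonymous) and
    the condition is flagged.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        syn = nonsyn = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    flagged = not valid
    if flagged:
        # no stop-free ordering exists: fall back to all orderings, counting
        # every step into or out of a stop as nonsynonymous
        valid = []
        for order in itertools.permutations(diff_pos):
            syn = nonsyn = 0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur] and GENETIC_CODE[nxt] != "*":
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            valid.append((syn, nonsyn))
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd, flagged


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for one aligned coding pair.

    Site counts are averaged between the two sequences (S̄ + N̄ = 3 ×
    codons exactly); differences are pathwise-averaged per codon; rates
    are Jukes–Cantor corrected.  pS or pN at or beyond the correction's
    3/4 ceiling leaves the corresponding rate undefined (saturation); the
    ratio is undefined when Ks is 0 or either rate is undefined.
    """
    s1 = sum(_syn_sites(c1) for c1, _ in aln.codons())
    s2 = sum(_syn_sites(c2) for _, c2 in aln.codons())
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * aln.n_codons - s_sites

    sd = nd = 0.0
    stop_only = False
    for c1, c2 in aln.codons():
        d_s, d_n, flagged = _codon_differences(c1, c2)
        sd += d_s
        nd += d_n
        stop_only = stop_only or flagged

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    if saturated or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(
        aln.pair_id, aln.label, s_sites, n_sites, sd, nd, ps, pn, ks, ka,
        ratio, saturated, stop_only,
    )


# ---------------------------------------------------------------------------
# Class contrast


@dataclass
class ClassContrast:
    """2×2 (class × ratio>1 / ratio<1) contrast with a Pearson chi-squared test."""

    table: np.ndarray  # rows: core, flexible; cols: ratio>1, ratio<1
    per_class: dict[str, dict]
    chi2_stat: float
    p_value: float
    excluded: dict[str, int]  # pairs with ratio undefined or exactly 1, per class
    expected_cell_warning: bool


def _contrast_from_counts(
    counts: dict[str, tuple[int, int, int]]
) -> ClassContrast:
    """Build the contrast from per-class (gt1, lt1, total_pairs) counts."""
    table = np.array(
        [[counts["core"][0], counts["core"][1]],
         [counts["flexible"][0], counts["flexible"][1]]],
        dtype=float,
    )
    per_class = {}
    excluded = {}
    for cls in ("core", "flexible"):
        gt1, lt1, total = counts[cls]
        if total <= 0:
            raise ValueError(f"no classified pairs for class {cls!r}")
        per_class[cls] = {
            "gt1": gt1, "lt1": lt1, "total": total, "pct_gt1": pct(gt1, total)
        }
        excluded[cls] = total - gt1 - lt1

    # Pearson chi-squared without continuity correction, 1 df
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    warn = bool((expected < 1).any())
    if warn:
        logger.warning("expected cell below 1; an exact test is recommended")
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return ClassContrast(table, per_class, stat, p, excluded, warn)


def compare_kaks_classes(
    core_results: Sequence[KaKsResult], flexible_results: Sequence[KaKsResult]
) -> ClassContrast:
    """Contrast the proportion of Ka/Ks > 1 pairs between core and flexible genes.

    Pairs with an undefined ratio or a ratio of exactly 1 are tallied as
    excluded and enter neither the 2×2 table nor its margins; the reported
    percentage of >1 pairs is taken over all pairs of the class.
    """
    counts = {}
    for cls, results in (("core", core_results), ("flexible", flexible_results)):
        gt1 = sum(1 for r in results if not math.isnan(r.ratio) and r.ratio > 1)
        lt1 = sum(1 for r in results if not math.isnan(r.ratio) and r.ratio < 1)
        counts[cls] = (gt1, lt1, len(results))
    return _contrast_from_counts(counts)


def class_contrast_from_counts(
    core_gt1: int,
    core_lt1: int,
    flexible_gt1: int,
    flexible_lt1: int,
    core_total: int | None = None,
    flexible_total: int | None = None,
) -> ClassContrast:
    """Contrast from tabulated counts (e.g. a published pair-count table)."""
    return _contrast_from_counts(
        {
            "core": (core_gt1, core_lt1, core_total or core_gt1 + core_lt1),
            "flexible": (
                flexible_gt1, flexible_lt1,
                flexible_total or flexible_gt1 + flexible_lt1,
            ),
        }
    )
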