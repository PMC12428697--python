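"""Population-genetic selection scan.

SNP filtering (bi-allelic, quality, call rate, minor-allele frequency),
per-site Weir–Cockerham (1984) FST variance components, windowed
ratio-of-sums FST, a composite-likelihood sweep score per window
(a desk-scale analogue of cross-population CLR scans), and the
intersection of the top-decile windows of both statistics into selection
intervals with the genes they contain.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, norm

from panpav.containers import MISSING, VariantPanel

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = (1.0, 1.5, 2.0, 5.0, 10.0, 20.0, 50.0)


# ---------------------------------------------------------------------------
# Filtering


def filter_variants(
    panel: VariantPanel,
    min_qual: float = 10.0,
    min_call_rate: float = 0.7,
    min_maf: float = 0.05,
) -> tuple[VariantPanel, dict[str, int]]:
    """Keep bi-allelic SNPs with qual > *min_qual*, call rate > *min_call_rate*
    and minor-allele frequency > *min_maf* (all strict).

    Returns the filtered panel and a tally of sites removed per rule;
    each removed site is charged to the first rule it fails, in the order
    multi-allelic, quality, call rate, MAF.
    """
    tally = {"multi_allelic": 0, "low_qual": 0, "low_call_rate": 0, "low_maf": 0}
    if panel.n_sites == 0:
        return panel, tally

    sites = panel.sites
    biallelic = (
        ~sites["alt"].astype(str).str.contains(",")
        & (sites["alt"].astype(str).str.len() == 1)
        & (sites["ref"].astype(str).str.len() == 1)
        & (sites["alt"].astype(str) != ".")
    ).to_numpy()
    qual_ok = (sites["qual"].to_numpy() > min_qual) & ~sites["qual"].isna().to_numpy()

    called = panel.genotypes != MISSING
    n_called = called.sum(axis=1)
    call_ok = n_called > min_call_rate * panel.n_samples

    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, panel.genotypes, 0).sum(axis=1)
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    maf_ok = maf > min_maf

    keep = biallelic & qual_ok & call_ok & maf_ok
    tally["multi_allelic"] = int((~biallelic).sum())
    tally["low_qual"] = int((biallelic & ~qual_ok).sum())
    tally["low_call_rate"] = int((biallelic & qual_ok & ~call_ok).sum())
    tally["low_maf"] = int((biallelic & qual_ok & call_ok & ~maf_ok).sum())
    return panel.take_sites(keep), tally


# ---------------------------------------------------------------------------
# Weir–Cockerham FST


def _pop_site_stats(panel: VariantPanel, pop: str):
    """Per-site (n_called, alt frequency, het fraction) for one population."""
    g = panel.genotypes[:, panel.sample_indices(pop)]
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / (2.0 * n)
        h = ((g == 1) & called).sum(axis=1) / n
    return n, p, h


def wc_fst_sites(panel: VariantPanel, pops: tuple[str, str]) -> pd.DataFrame:
    """Per-site Weir–Cockerham (1984) variance components for two populations.

    Returns a frame with ``chrom``, ``pos``, components ``a`` (among
    populations), ``b`` (among individuals within populations), ``c``
    (within individuals), and ``theta`` = a/(a+b+c) (NaN where the site is
    monomorphic or a population has no called genotype).
    """
    n1, p1, h1 = _pop_site_stats(panel, pops[0])
    n2, p2, h2 = _pop_site_stats(panel, pops[1])
    r = 2.0

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0

        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    valid = (n1 > 0) & (n2 > 0) & (nbar > 1)
    out = pd.DataFrame(
        {
            "chrom": panel.sites["chrom"].to_numpy(),
            "pos": panel.sites["pos"].to_numpy(),
            "a": np.where(valid, a, np.nan),
            "b": np.where(valid, b, np.nan),
            "c": np.where(valid, c, np.nan),
        }
    )
    out["theta"] = np.where(valid, theta, np.nan)
    return out


# ---------------------------------------------------------------------------
# Windows


def _make_windows(
    chrom_extent: Mapping[str, int], window_size: int, step: int
) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_extent):
        end = int(chrom_extent[chrom])
        start = 0
        while start < end:
            rows.append({"chrom": chrom, "start": start, "end": start + window_size})
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _rank_windows(track: pd.DataFrame) -> pd.DataFrame:
    """Attach 1-based ranks: highest score first, ties by (chrom, start)."""
    order = track.sort_values(
        by=["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).index
    track = track.copy()
    track.loc[order, "rank"] = np.arange(1, len(track) + 1)
    track["rank"] = track["rank"].astype(int)
    return track


def window_aggregate(
    fst_sites: pd.DataFrame,
    window_size: int = 100_000,
    step: int | None = None,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Windowed FST as a ratio of sums: sum(a) / sum(a+b+c) over defined sites.

    Windows (0-based half-open) tile each chromosome from 0 past the last
    site; windows with fewer than *min_sites* defined sites are dropped.
    Returns a window track: ``chrom, start, end, score, n_sites, rank``.
    """
    step = step or window_size
    defined = fst_sites.dropna(subset=["theta"])
    if defined.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "n_sites", "rank"])
    extent = defined.groupby("chrom")["pos"].max().to_dict()
    windows = _make_windows(extent, window_size, step)

    rows = []
    for _, w in windows.iterrows():
        sub = defined[
            (defined["chrom"] == w["chrom"])
            & (defined["pos"] - 1 >= w["start"])
            & (defined["pos"] - 1 < w["end"])
        ]
        if len(sub) < min_sites:
            continue
        denom = (sub["a"] + sub["b"] + sub["c"]).sum()
        if denom <= 0:
            continue
        rows.append(
            {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "score": sub["a"].sum() / denom,
                "n_sites": len(sub),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "n_sites", "rank"])
    return _rank_windows(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Composite-likelihood sweep score


def clr_scan(
    panel: VariantPanel,
    object_pop: str,
    reference_pop: str,
    window_size: int = 100_000,
    step: int | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    quadrature_nodes: int = 64,
    min_informative: int = 50,
) -> pd.DataFrame:
    """Variance-inflation composite-likelihood sweep scan.

    Under drift, the object population's allele frequency is modelled as a
    normal around the reference frequency with variance ω·p(1−p),
    truncated to [0, 1]; ω̂ is estimated genome-wide from sites with
    reference frequency in (0.05, 0.95).  Per window, the score is
    2·(max over the λ grid of the summed site log-likelihoods at variance
    λ·ω̂·p(1−p), minus the sum at λ = 1).  λ = 1 belongs to the grid, so
    scores are non-negative; a sweep inflates local differentiation and
    favours λ > 1.  The scan is fully deterministic (fixed Gauss–Legendre
    quadrature, no sampling).
    """
    step = step or window_size
    lambda_grid = sorted(set(float(l) for l in lambda_grid) | {1.0})

    n_ref, p_ref, _ = _pop_site_stats(panel, reference_pop)
    g_obj = panel.genotypes[:, panel.sample_indices(object_pop)]
    called_obj = g_obj != MISSING
    n_obj = 2 * called_obj.sum(axis=1)
    x_obj = np.where(called_obj, g_obj, 0).sum(axis=1)

    usable = (n_ref > 0) & (n_obj > 0) & (p_ref > 0.05) & (p_ref < 0.95)
    n_usable = int(usable.sum())
    if n_usable < min_informative:
        raise ValueError(
            f"only {n_usable} informative sites; need >= {min_informative} to estimate omega"
        )
    p_obj = np.where(n_obj > 0, x_obj / np.maximum(n_obj, 1), np.nan)
    base_var = p_ref * (1.0 - p_ref)
    omega = float(
        np.mean((p_obj[usable] - p_ref[usable]) ** 2 / base_var[usable])
    )

    pos = panel.sites["pos"].to_numpy()[usable]
    chroms = panel.sites["chrom"].to_numpy()[usable]
    xs, ns = x_obj[usable], n_obj[usable]
    mu, bv = p_ref[usable], base_var[usable]

    nodes, weights = np.polynomial.legendre.leggauss(quadrature_nodes)
    p_nodes = (nodes + 1.0) / 2.0  # map [-1,1] -> [0,1]
    w_nodes = weights / 2.0

    log_binom = binom.logpmf(xs[:, None], ns[:, None], p_nodes[None, :])

    loglik = np.empty((len(xs), len(lambda_grid)))
    for j, lam in enumerate(lambda_grid):
        sigma = np.sqrt(lam * omega * bv)[:, None]
        z = (p_nodes[None, :] - mu[:, None]) / sigma
        dens = norm.pdf(z) / sigma
        mass = norm.cdf((1.0 - mu[:, None]) / sigma) - norm.cdf(-mu[:, None] / sigma)
        dens = dens / mass
        loglik[:, j] = logsumexp(log_binom + np.log(w_nodes[None, :] * dens), axis=1)

    null_idx = lambda_grid.index(1.0)
    extent = pd.Series(pos).groupby(pd.Series(chroms)).max().to_dict()
    windows = _make_windows(extent, window_size, step)

    rows = []
    for _, w in windows.iterrows():
        mask = (chroms == w["chrom"]) & (pos - 1 >= w["start"]) & (pos - 1 < w["end"])
        if not mask.any():
            continue
        sums = loglik[mask].sum(axis=0)
        rows.append(
            {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "score": 2.0 * (sums.max() - sums[null_idx]),
                "n_sites": int(mask.sum()),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "n_sites", "rank"])
    return _rank_windows(pd.DataFrame(rows))


def window_track_from_tsv(path) -> pd.DataFrame:
    """Load an externally computed window-score track (chrom, start, end, score).

    Accepts e.g. XP-CLR per-window output reshaped to four columns, so a
    real scan can replace the built-in composite-likelihood score.
    """
    track = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"]
    )
    track["n_sites"] = np.nan
    return _rank_windows(track)


# ---------------------------------------------------------------------------
# Interval intersection and gene lookup


def _merge_regions(regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(regions):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_regions(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return _merge_regions(out)


def _top_windows(track: pd.DataFrame, top_fraction: float) -> pd.DataFrame:
    m = math.ceil(top_fraction * len(track))
    return track.sort_values(
        by=["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).head(m)


def select_intervals(
    fst_track: pd.DataFrame,
    clr_track: pd.DataFrame,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Intersect the top-decile windows of two score tracks.

    The ceil(top_fraction·W) highest-scoring windows of each track (ties
    broken by score desc, then chrom, then start) are merged into regions;
    the genomic intersection of the two region sets, merged again, gives
    the selection intervals.  Each interval lists the contributing window
    (chrom, start) pairs from both tracks.
    """
    cols = ["chrom", "start", "end", "fst_windows", "clr_windows"]
    if fst_track.empty or clr_track.empty:
        logger.warning("empty window track; no selection intervals")
        return pd.DataFrame(columns=cols)

    top_f = _top_windows(fst_track, top_fraction)
    top_c = _top_windows(clr_track, top_fraction)

    rows = []
    for chrom in sorted(set(top_f["chrom"]) & set(top_c["chrom"])):
        rf = _merge_regions(
            list(zip(top_f.loc[top_f["chrom"] == chrom, "start"],
                     top_f.loc[top_f["chrom"] == chrom, "end"]))
        )
        rc = _merge_regions(
            list(zip(top_c.loc[top_c["chrom"] == chrom, "start"],
                     top_c.loc[top_c["chrom"] == chrom, "end"]))
        )
        for s, e in _intersect_regions(rf, rc):
            contrib_f = [
                (chrom, int(w.start))
                for w in top_f[top_f["chrom"] == chrom].itertuples()
                if w.start < e and s < w.end
            ]
            contrib_c = [
                (chrom, int(w.start))
                for w in top_c[top_c["chrom"] == chrom].itertuples()
                if w.start < e and s < w.end
            ]
            rows.append(
                {"chrom": chrom, "start": s, "end": e,
                 "fst_windows": contrib_f, "clr_windows": contrib_c}
            )
    return pd.DataFrame(rows, columns=cols)


def genes_in_intervals(
    intervals: pd.DataFrame,
    gene_models: pd.DataFrame,
    origin_classifier: Callable[[str], str] | Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes overlapping any selection interval by at least 1 bp.

    *gene_models* needs columns ``gene``, ``chrom``, ``start``, ``end``
    (0-based half-open, as produced by :func:`panpav.io.read_gff3_genes`).
    *origin_classifier* maps a sequence ID to ``"reference"`` or
    ``"non_reference"``; a sequence it does not know is tallied as
    non-reference with a warning.  Returns the overlapping genes with
    their origins, and the per-origin tally.
    """
    def classify(chrom: str) -> str:
        if origin_classifier is None:
            return "reference"
        try:
            if callable(origin_classifier):
                return origin_classifier(chrom)
            return origin_classifier[chrom]
        except KeyError:
            logger.warning("sequence %s unknown to origin classifier", chrom)
            return "non_reference"

    rows = []
    for g in gene_models.itertuples():
        hit = intervals[
            (intervals["chrom"] == g.chrom)
            & (intervals["start"] < g.end)
            & (g.start < intervals["end"])
        ]
        if not hit.empty:
            rows.append(
                {"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end,
                 "origin": classify(g.chrom)}
            )
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "origin"])
    tally = {
        "reference": int((genes["origin"] == "reference").sum()),
        "non_reference": int((genes["origin"] == "non_reference").sum()),
    }
    return genes, tally
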