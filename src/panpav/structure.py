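"""Population structure: distance matrices, neighbor-joining trees, PCA.

SNP distances are allele-sharing p-distances (mean per-site half allele
difference over shared called sites); PAV distances are Jaccard or Hamming
on present-gene sets.  Trees are built by Saitou–Nei neighbor joining with
a deterministic tie-break; PCA is an SVD on the centred (optionally
scaled) sample × feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from panpav.containers import MISSING, VariantPanel, validate_pav

logger = logging.getLogger(__name__)


def _check_distance(d: pd.DataFrame) -> pd.DataFrame:
    m = d.to_numpy()
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError("distance matrix diagonal not zero")
    if not np.isfinite(m).all():
        raise ValueError("non-finite distances")
    return d


# ---------------------------------------------------------------------------
# Distances


def snp_p_distance(panel: VariantPanel, min_shared_sites: int = 50) -> pd.DataFrame:
    """Pairwise allele-sharing p-distance from diploid dosages.

    Per shared called site the distance is half the number of differing
    alleles between the two genotypes (0, 0.5 or 1); the pairwise distance
    is the mean over shared sites.  A pair sharing fewer than
    *min_shared_sites* called sites is an error.
    """
    g = panel.genotypes.astype(float)
    called = g != MISSING
    n = panel.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        shared = called[:, [i]] & called[:, i + 1 :]
        n_shared = shared.sum(axis=0)
        short = np.flatnonzero(n_shared < min_shared_sites)
        if short.size:
            j = i + 1 + short[0]
            raise ValueError(
                f"samples {panel.samples[i]!r} and {panel.samples[j]!r} share only "
                f"{int(n_shared[short[0]])} called sites (< {min_shared_sites})"
            )
        diff = np.abs(g[:, [i]] - g[:, i + 1 :]) / 2.0
        d[i, i + 1 :] = np.where(shared, diff, 0.0).sum(axis=0) / n_shared
    d = d + d.T
    return _check_distance(pd.DataFrame(d, index=panel.samples, columns=panel.samples))


def pav_distance(pav: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise sample distance from a PAV matrix.

    ``jaccard``: 1 − |intersection| / |union| of present-gene sets (two
    empty sets are at distance 0, an empty vs non-empty set at 1).
    ``hamming``: mismatch fraction over all genes.
    """
    validate_pav(pav)
    m = pav.to_numpy(dtype=np.float64)
    if not (m.any(axis=1).any()):
        logger.warning("no gene varies or is present; distances degenerate")
    if metric == "jaccard":
        inter = m.T @ m
        sizes = m.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        d[union == 0] = 0.0  # both sets empty
    elif metric == "hamming":
        diff = m.T @ (1 - m) + (1 - m).T @ m
        d = diff / m.shape[0]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return _check_distance(pd.DataFrame(d, index=pav.columns, columns=pav.columns))


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class NJTree:
    """An unrooted neighbor-joining tree in newick form."""

    newick: str
    negative_branches: list[tuple[str, float]]

    @property
    def has_negative_branches(self) -> bool:
        return bool(self.negative_branches)


def neighbor_joining(d: pd.DataFrame) -> NJTree:
    """Saitou–Nei neighbor joining on a distance matrix.

    At each step the pair minimising Q(i,j) = (r−2)·d(i,j) − R_i − R_j is
    joined; ties are broken deterministically by the smaller (i, j) index
    pair in the current matrix order.  Branch lengths use the standard
    formulas and may be negative; negative branches are reported (flagged),
    never clamped.
    """
    _check_distance(d)
    labels = [str(s) for s in d.index]
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    dm = d.to_numpy(dtype=float).copy()
    # newick fragments: (content, is_internal); internal content lacks outer parens
    nodes: list[tuple[str, bool]] = [(lab, False) for lab in labels]
    names = list(labels)  # display names for flag reporting
    negative: list[tuple[str, float]] = []

    def fmt(length: float) -> str:
        return f"{length:.10g}"

    def wrap(node: tuple[str, bool]) -> str:
        content, internal = node
        return f"({content})" if internal else content

    while len(nodes) > 2:
        r = len(nodes)
        row_sums = dm.sum(axis=1)
        q = (r - 2) * dm - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic arg-min: smallest Q, then smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = min(best), max(best)

        li = 0.5 * dm[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dm[i, j] - li
        for name, length in ((names[i], li), (names[j], lj)):
            if length < 0:
                negative.append((name, float(length)))

        new_node = (f"{wrap(nodes[i])}:{fmt(li)},{wrap(nodes[j])}:{fmt(lj)}", True)
        new_name = f"({names[i]},{names[j]})"
        new_dist = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])

        keep = [k for k in range(r) if k not in (i, j)]
        dm = np.vstack([dm[keep][:, keep], new_dist[keep][None, :]])
        dm = np.hstack([dm, np.append(new_dist[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new_node]
        names = [names[k] for k in keep] + [new_name]

    # attach the remaining edge; the root is a trifurcation when possible
    final = dm[0, 1]
    if final < 0:
        negative.append((names[0], float(final)))
    (c0, int0), (c1, int1) = nodes
    if int1:
        newick = f"({c1},{wrap(nodes[0])}:{fmt(final)});"
    elif int0:
        newick = f"({c0},{c1}:{fmt(final)});"
    else:  # two leaves cannot occur for n >= 3 input, kept for safety
        newick = f"({c0}:{fmt(final)},{c1}:0);"
    if negative:
        logger.warning("tree has %d negative branch length(s)", len(negative))
    return NJTree(newick, negative)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples × PCs
    explained_ratio: np.ndarray
    components: np.ndarray  # PCs × features (orthonormal rows)


def genotype_feature_matrix(panel: VariantPanel) -> pd.DataFrame:
    """Samples × sites alt-dosage matrix with missing dosages mean-imputed."""
    g = panel.genotypes.astype(float).T  # samples × sites
    miss = g == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, g).mean(axis=0, where=~miss)
        col_mean = np.nan_to_num(col_mean)
        g = np.where(miss, col_mean[None, :], g)
    return pd.DataFrame(g, index=panel.samples)


def pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """Principal component analysis by singular value decomposition.

    Columns (features) are centred and optionally scaled to unit variance;
    zero-variance features are dropped (with a log entry) when scaling.
    Variance-explained fractions are squared singular values over their
    total.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.info("dropping %d zero-variance features before scaling", zero.sum())
            x = x[:, ~zero]
            sd = sd[~zero]
        x = x / sd
    if not (x != x[0]).any():
        raise ValueError("no varying feature")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = n_components or min(x.shape)
    k = min(k, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coords, explained[:k], vt[:k])
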