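"""Core / softcore / shell / cloud partitioning and pan-genome size modelling.

A gene's presence frequency f = (number of samples carrying it) / N places
it in one of four classes:

* **core** — present in every sample (f = 1 exactly),
* **softcore** — 0.99 <= f < 1,
* **shell** — 0.01 < f < 0.99,
* **cloud** — 0 < f <= 0.01.

Genes absent from every sample are reported separately ("absent
everywhere") and excluded from class percentages.  Shell + cloud together
form the *flexible* (dispensable) genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from panpav.containers import validate_pav

logger = logging.getLogger(__name__)

CLASSES = ("core", "softcore", "shell", "cloud")


def classify_frequency(f: float) -> str:
    """Classify a presence frequency in (0, 1] into a partition band."""
    if not 0.0 < f <= 1.0:
        raise ValueError("frequency must be in (0, 1]")
    if f == 1.0:
        return "core"
    if f >= 0.99:
        return "softcore"
    if f > 0.01:
        return "shell"
    return "cloud"


def classify_count(count: int, n_samples: int) -> str:
    """Classify a presence count out of *n_samples* (count >= 1)."""
    if count == n_samples:
        return "core"
    return classify_frequency(count / n_samples)


def pct(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage rounded half-up at *decimals* (the convention of printed tables)."""
    if whole == 0:
        raise ValueError("cannot take a percentage of zero")
    q = Decimal(10) ** -decimals
    return float(Decimal(100 * part / whole).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PartitionResult:
    """Per-gene classes plus per-class tallies for a PAV matrix."""

    table: pd.DataFrame  # columns: count, frequency, class (index = gene)
    n_samples: int
    class_counts: dict[str, int]
    absent_everywhere: list[str]

    @property
    def classified_total(self) -> int:
        return sum(self.class_counts.values())


def classify_genes(pav: pd.DataFrame) -> PartitionResult:
    """Partition a PAV matrix's genes by presence frequency."""
    validate_pav(pav)
    if pav.shape[0] == 0 or pav.shape[1] == 0:
        raise ValueError("empty PAV matrix")
    n = pav.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to partition")

    counts = pav.sum(axis=1).astype(int)
    absent = counts.index[counts == 0].tolist()
    present = counts[counts > 0]
    labels = present.map(lambda c: classify_count(int(c), n))
    table = pd.DataFrame(
        {
            "count": present,
            "frequency": present / n,
            "class": pd.Categorical(labels, categories=CLASSES),
        }
    )
    class_counts = {cls: int((table["class"] == cls).sum()) for cls in CLASSES}
    return PartitionResult(table, n, class_counts, absent)


def partition_summary(
    partition: PartitionResult | Mapping[str, int],
    total_detected: int | None = None,
) -> dict:
    """Counts and percentages per class, plus the flexible (shell+cloud) total.

    Accepts either a :class:`PartitionResult` or a plain mapping of class
    counts (so printed tables can be summarised directly).  When
    *total_detected* is given (the number of genes the PAV pipeline set out
    to score, including any it could not identify), an identified-fraction
    percentage is included.
    """
    if isinstance(partition, PartitionResult):
        counts = partition.class_counts
    else:
        counts = {cls: int(partition.get(cls, 0)) for cls in CLASSES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified genes to summarise")

    summary: dict = {
        "classes": {
            cls: {"count": counts[cls], "pct": pct(counts[cls], total)}
            for cls in CLASSES
        },
        "classified_total": total,
        "flexible": {
            "count": counts["shell"] + counts["cloud"],
            "pct": pct(counts["shell"] + counts["cloud"], total),
        },
    }
    if total_detected is not None:
        summary["total_detected"] = int(total_detected)
        summary["identified_pct"] = pct(total, total_detected)
    return summary


def sample_gene_counts(
    pav: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample gene totals and per-group summaries.

    Unmapped samples fall into group ``"ungrouped"``.  The group table
    reports mean, median, min, max and the sample IDs attaining the
    extremes.
    """
    validate_pav(pav)
    totals = pav.sum(axis=0).astype(int)
    totals.name = "n_genes"
    groups = groups or {}
    grp = pd.Series(
        [groups.get(s, "ungrouped") for s in pav.columns], index=pav.columns
    )
    rows = []
    for name, members in totals.groupby(grp):
        rows.append(
            {
                "group": name,
                "n_samples": len(members),
                "mean": members.mean(),
                "median": members.median(),
                "min": int(members.min()),
                "max": int(members.max()),
                "min_sample": members.idxmin(),
                "max_sample": members.idxmax(),
            }
        )
    return totals, pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Rarefaction ("sample filling") and growth models


@dataclass
class RarefactionCurve:
    """Pan (union) and core (intersection) gene counts over subset sizes."""

    table: pd.DataFrame  # index k=1..N; columns pan_mean/min/max, core_mean/min/max
    replicates: int
    seed: int

    @property
    def k(self) -> np.ndarray:
        return self.table.index.to_numpy()


def rarefaction_curves(
    pav: pd.DataFrame, replicates: int = 100, seed: int = 0
) -> RarefactionCurve:
    """Resample k = 1..N samples and track pan and core genome sizes.

    Each replicate draws one uniform random permutation of the samples and
    accumulates the gene union (pan) and intersection (core) along its
    prefixes — a length-k prefix is a uniform k-subset drawn without
    replacement, and coupling the subsets across k makes the replicate
    means exactly monotone (pan non-decreasing, core non-increasing) for
    every seed.  Permutations are drawn independently per replicate, so
    subsets recur across replicates when R exceeds the number of distinct
    ones.
    """
    validate_pav(pav)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mat = pav.to_numpy(dtype=bool)
    n = mat.shape[1]

    pans = np.empty((replicates, n), dtype=np.int64)
    cores = np.empty((replicates, n), dtype=np.int64)
    for r in range(replicates):
        order = rng.permutation(n)
        cum_any = np.logical_or.accumulate(mat[:, order], axis=1)
        cum_all = np.logical_and.accumulate(mat[:, order], axis=1)
        pans[r] = cum_any.sum(axis=0)
        cores[r] = cum_all.sum(axis=0)

    table = pd.DataFrame(
        {
            "pan_mean": pans.mean(axis=0),
            "pan_min": pans.min(axis=0),
            "pan_max": pans.max(axis=0),
            "core_mean": cores.mean(axis=0),
            "core_min": cores.min(axis=0),
            "core_max": cores.max(axis=0),
        },
        index=pd.Index(np.arange(1, n + 1), name="k"),
    )
    return RarefactionCurve(table, replicates, seed)


@dataclass
class GrowthFit:
    """Least-squares fit of one rarefaction curve."""

    model: str  # "power" (A·k^B + C) or "exponential" (A·e^(−k/tau) + Omega)
    params: dict[str, float]
    residual_norm: float
    saturated: bool
    converged: bool


def _marginal_gain(model: str, params: dict[str, float], n: int) -> float:
    if model == "power":
        f = lambda k: params["A"] * k ** params["B"] + params["C"]
    else:
        f = lambda k: params["A"] * math.exp(-k / params["tau"]) + params["Omega"]
    return abs(f(n) - f(n - 1))


def _fit(model: str, k: np.ndarray, y: np.ndarray) -> GrowthFit:
    if model == "power":
        fun = lambda k, A, B, C: A * np.power(k, B) + C
        span = y[-1] - y[0]
        p0 = [span if abs(span) > 1e-9 else 1.0, 0.5, y[0]]
        names = ["A", "B", "C"]
    else:
        fun = lambda k, A, tau, Omega: A * np.exp(-k / tau) + Omega
        span = y[0] - y[-1]
        p0 = [span if abs(span) > 1e-9 else 1.0, max(len(k) / 4.0, 1.0), y[-1]]
        names = ["A", "tau", "Omega"]
    try:
        popt, _ = curve_fit(
            fun, k.astype(float), y.astype(float), p0=p0, maxfev=20000,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        converged = True
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    params = dict(zip(names, map(float, popt)))
    resid = float(np.linalg.norm(y - fun(k.astype(float), *popt)))
    level = abs(fun(float(k[-1]), *popt))
    saturated = converged and _marginal_gain(model, params, int(k[-1])) < 1e-3 * max(
        level, 1e-12
    )
    if not converged:
        logger.warning("%s growth model did not converge (residual norm %.3g)", model, resid)
    return GrowthFit(model, params, resid, saturated, converged)


def fit_growth_models(curve: RarefactionCurve) -> dict[str, GrowthFit]:
    """Fit the pan curve to a power law and the core curve to exponential decay.

    Pan: P(k) = A·k^B + C.  Core: C(k) = A·e^(−k/tau) + Omega.  Both by
    unweighted least squares on the replicate means.  A curve is flagged
    *saturated* when the fitted marginal gain from the last added sample is
    below 0.1% of the fitted level.
    """
    if len(curve.table) < 4:
        raise ValueError("need a curve with at least 4 subset sizes")
    k = curve.k
    return {
        "pan": _fit("power", k, curve.table["pan_mean"].to_numpy()),
        "core": _fit("exponential", k, curve.table["core_mean"].to_numpy()),
    }
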