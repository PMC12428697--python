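"""Synthetic pan-genome data with known ground truth.

Every downstream stage of the pipeline (presence calling, partitioning,
selection scans, trees/PCA, Ka/Ks) can be exercised on data from this
module and checked against the recorded truth:

* :func:`sim_pav` — a PAV matrix whose genes are drawn inside configured
  presence-frequency bands per class (core / softcore / shell / cloud).
* :func:`sim_coverage` — bimodal Beta-distributed coverage breadths for
  present vs absent genes, gene-body and CDS breadth positively correlated.
* :func:`sim_genotypes` — a structured diploid SNP panel under the
  Balding–Nichols drift model, with optional deterministic selective-sweep
  frequency displacement in a target population.
* :func:`sim_codon_pairs` — codon-alignment pairs mutated at a target
  nonsynonymous/synonymous ratio, with realized change counts recorded.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from panpav.containers import VariantPanel
from panpav.molevol import CodonAlignment, GENETIC_CODE, SENSE_CODONS
from panpav.pangenome import CLASSES, classify_count, classify_frequency

# Default gene complement: the four class proportions of a ~32k-gene plant
# pan-genome scaled to 1000 genes, scored across 109 accessions.
DEFAULT_GENES_PER_CLASS = {"core": 719, "softcore": 61, "shell": 208, "cloud": 12}

# Presence-frequency sampler bounds per class; each nests strictly inside
# the partition band used by pangenome.classify_genes.
DEFAULT_FREQ_BOUNDS = {
    "core": (1.0, 1.0),
    "softcore": (0.99, 0.9999),
    "shell": (0.02, 0.98),
    "cloud": (0.0001, 0.01),
}


@dataclass(frozen=True)
class SimPavConfig:
    n_samples: int = 109
    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CLASS)
    )
    freq_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FREQ_BOUNDS)
    )
    seed: int = 0


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    target_pop: str
    intensity: float


@dataclass(frozen=True)
class SimPopConfig:
    n_pops: int = 4
    samples_per_pop: tuple[int, ...] = (30, 30, 25, 24)
    n_sites: int = 20_000
    drift: tuple[float, ...] | float = 0.2  # Balding–Nichols F per population
    sweeps: tuple[SweepRegion, ...] = ()
    ancestral_bounds: tuple[float, float] = (0.05, 0.95)
    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    seed: int = 0

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    def drift_per_pop(self) -> list[float]:
        if isinstance(self.drift, (int, float)):
            return [float(self.drift)] * self.n_pops
        return [float(f) for f in self.drift]


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset (fields used as relevant)."""

    gene_class: dict[str, str] = field(default_factory=dict)
    gene_freq: dict[str, float] = field(default_factory=dict)
    sample_pop: dict[str, str] = field(default_factory=dict)
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    pair_changes: dict[str, tuple[int, int]] = field(default_factory=dict)
    """pair ID -> (synonymous, nonsynonymous) realized single-step changes."""
    pop_freqs: "np.ndarray | None" = None
    """(n_pops, n_sites) realized population allele frequencies (post-sweep)."""


# ---------------------------------------------------------------------------
# PAV matrix


def _band_count_range(cls: str, n_samples: int) -> tuple[int, int]:
    """Inclusive range of presence counts classified as *cls* for N samples."""
    counts = [c for c in range(1, n_samples + 1) if classify_count(c, n_samples) == cls]
    if not counts:
        raise ValueError(
            f"class {cls!r} has no attainable presence count with {n_samples} samples"
        )
    return counts[0], counts[-1]


def sim_pav(config: SimPavConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a PAV matrix with genes drawn inside per-class frequency bands.

    Each gene's presence frequency is drawn uniformly inside its class's
    configured bounds and realized as a presence count rounded (and clamped)
    into the class's attainable count range, so the realized frequency of
    every gene classifies back into its own band.  Present samples are
    chosen uniformly without replacement.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    total_genes = sum(config.n_genes_per_class.values())
    if total_genes == 0:
        raise ValueError("at least one gene must be requested")
    for cls, (lo, hi) in config.freq_bounds.items():
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"frequency bounds for {cls!r} must satisfy 0 < lo <= hi <= 1")
        if config.n_genes_per_class.get(cls, 0) and not (
            classify_frequency(lo) == classify_frequency(hi) == cls
        ):
            raise ValueError(f"frequency bounds for {cls!r} escape the {cls} band")

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    width = len(str(total_genes))

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth = SimTruth()
    gene_no = 0
    for cls in CLASSES:
        n_genes = config.n_genes_per_class.get(cls, 0)
        if n_genes == 0:
            continue
        lo, hi = config.freq_bounds[cls]
        cmin, cmax = _band_count_range(cls, n)
        freqs = rng.uniform(lo, hi, size=n_genes)
        counts = np.clip(np.rint(freqs * n).astype(int), cmin, cmax)
        for f, count in zip(freqs, counts):
            gene_no += 1
            gid = f"g{gene_no:0{width}d}"
            row = np.zeros(n, dtype=np.int8)
            row[rng.choice(n, size=count, replace=False)] = 1
            gene_ids.append(gid)
            rows.append(row)
            truth.gene_class[gid] = cls
            truth.gene_freq[gid] = float(f)

    pav = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=samples)
    pav.index.name = "gene"
    return pav, truth


# ---------------------------------------------------------------------------
# Coverage breadth


def _beta_around(rng, mean: np.ndarray, concentration: float) -> np.ndarray:
    """Beta draws with the given per-element mean; degenerate means pass through."""
    out = np.array(mean, dtype=float, copy=True)
    inner = (mean > 0) & (mean < 1)
    if inner.any():
        m = mean[inner]
        out[inner] = rng.beta(m * concentration, (1.0 - m) * concentration)
    return out


def sim_coverage(
    pav: pd.DataFrame,
    present_breadth_mean: float = 0.95,
    absent_breadth_mean: float = 0.05,
    concentration: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-(gene, sample) coverage breadths from a PAV truth matrix.

    A latent per-cell mean is drawn from a Beta centred on the present or
    absent breadth mean, and gene-body and CDS breadths are then drawn
    around the shared latent — making the two breadths positively
    correlated while preserving the configured marginal means.
    """
    if not (0.0 <= absent_breadth_mean < present_breadth_mean <= 1.0):
        raise ValueError("need 0 <= absent mean < present mean <= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)

    presence = pav.to_numpy().astype(bool).ravel()
    means = np.where(presence, present_breadth_mean, absent_breadth_mean)
    latent = np.clip(_beta_around(rng, means, concentration), 1e-9, 1 - 1e-9)
    latent[means == 0.0] = 0.0
    latent[means == 1.0] = 1.0
    gene_breadth = _beta_around(rng, latent, concentration)
    cds_breadth = _beta_around(rng, latent, concentration)

    genes = np.repeat(pav.index.to_numpy(), pav.shape[1])
    samples = np.tile(pav.columns.to_numpy(), pav.shape[0])
    return pd.DataFrame(
        {
            "gene": genes,
            "sample": samples,
            "gene_breadth": gene_breadth,
            "cds_breadth": cds_breadth,
        }
    )


# ---------------------------------------------------------------------------
# Structured genotypes (Balding–Nichols with deterministic sweeps)


def sim_genotypes(config: SimPopConfig) -> tuple[VariantPanel, SimTruth]:
    """Simulate a structured diploid SNP panel.

    Per site: the ancestral allele frequency is uniform within
    ``ancestral_bounds``; each population's frequency is Beta-distributed
    with mean p and variance F·p(1−p) (Balding–Nichols); genotypes are
    Binomial(2, population frequency).  Within a sweep region the target
    population's frequency is displaced toward its nearer boundary:
    p' = p + intensity·(round(p) − p).
    """
    if len(config.samples_per_pop) != config.n_pops:
        raise ValueError("samples_per_pop length must equal n_pops")
    drifts = config.drift_per_pop()
    for f in drifts:
        if not (0.0 < f < 1.0):
            raise ValueError("drift F must be strictly in (0, 1)")
    for sw in config.sweeps:
        if not (0.0 <= sw.intensity <= 1.0):
            raise ValueError("sweep intensity must be in [0, 1]")
        if not (0 <= sw.start < sw.end <= config.chrom_length):
            raise ValueError("sweep region outside the simulated chromosome")
        if sw.target_pop not in config.pop_names:
            raise ValueError(f"unknown sweep target population {sw.target_pop!r}")

    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites

    # distinct sorted positions; collisions at this density are rare
    positions = np.unique(rng.integers(1, config.chrom_length + 1, size=n_sites))
    while len(positions) < n_sites:
        extra = rng.integers(1, config.chrom_length + 1, size=n_sites)
        positions = np.unique(np.concatenate([positions, extra]))
    positions = np.sort(rng.choice(positions, size=n_sites, replace=False))

    anc = rng.uniform(*config.ancestral_bounds, size=n_sites)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    pop_freqs = []
    for f in drifts:
        scale = (1.0 - f) / f
        pop_freqs.append(rng.beta(anc * scale, (1.0 - anc) * scale))

    for sw in config.sweeps:
        k = config.pop_names.index(sw.target_pop)
        in_region = (positions - 1 >= sw.start) & (positions - 1 < sw.end)
        p = pop_freqs[k]
        target = np.rint(p[in_region])
        p[in_region] = p[in_region] + sw.intensity * (target - p[in_region])

    blocks, samples = [], []
    truth = SimTruth(
        sweep_regions=list(config.sweeps), pop_freqs=np.vstack(pop_freqs)
    )
    for k, (name, n_k) in enumerate(zip(config.pop_names, config.samples_per_pop)):
        blocks.append(rng.binomial(2, pop_freqs[k][:, None], size=(n_sites, n_k)))
        for j in range(n_k):
            sid = f"{name}_s{j + 1:02d}"
            samples.append(sid)
            truth.sample_pop[sid] = name

    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "qual": rng.uniform(20.0, 60.0, size=n_sites),
        }
    )
    genotypes = np.hstack(blocks).astype(np.int8)
    panel = VariantPanel(sites, genotypes, samples, dict(truth.sample_pop))
    return panel, truth


# ---------------------------------------------------------------------------
# Codon-alignment pairs


def _single_step_changes(codon: str) -> list[tuple[int, str, bool]]:
    """All non-stop single-base changes of *codon* as (position, base, is_synonymous)."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == "*":
                continue
            out.append((pos, base, GENETIC_CODE[mutant] == aa))
    return out


def sim_codon_pairs(
    n_pairs: int = 50,
    target_omega: float = 0.3,
    n_codons: int = 300,
    mutations_per_pair: int = 30,
    seed: int = 0,
    label: str = "core",
) -> tuple[list[CodonAlignment], SimTruth]:
    """Simulate aligned coding-sequence pairs with labelled substitutions.

    One sequence of each pair accumulates single-base changes one at a
    time; each change is nonsynonymous with probability
    ω·N̄/(ω·N̄ + S̄), where S̄ and N̄ are the starting sequence's NG86
    synonymous and nonsynonymous site counts — the nonsynonymous rate per
    nonsynonymous site is thus ω times the synonymous rate per synonymous
    site, so the realized Ka/Ks tracks the target ω.  A codon offering no
    change of the requested type is resampled — changes are never
    mislabelled.  Stop codons are never created.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if target_omega < 0:
        raise ValueError("target_omega must be non-negative")
    rng = np.random.default_rng(seed)

    def syn_fraction(codons: list[str]) -> float:
        from panpav.molevol import _syn_sites

        return sum(_syn_sites(c) for c in codons) / (3.0 * len(codons))

    pairs, truth = [], SimTruth()
    for i in range(n_pairs):
        codons = list(rng.choice(SENSE_CODONS, size=n_codons))
        s_frac = syn_fraction(codons)
        n_frac = 1.0 - s_frac
        p_nonsyn = (
            target_omega * n_frac / (target_omega * n_frac + s_frac)
            if target_omega > 0
            else 0.0
        )
        mutant = codons.copy()
        syn = nonsyn = 0
        for _ in range(mutations_per_pair):
            want_nonsyn = rng.random() < p_nonsyn
            while True:
                j = int(rng.integers(n_codons))
                options = [
                    (pos, base)
                    for pos, base, is_syn in _single_step_changes(mutant[j])
                    if is_syn != want_nonsyn
                ]
                if options:
                    pos, base = options[int(rng.integers(len(options)))]
                    mutant[j] = mutant[j][:pos] + base + mutant[j][pos + 1 :]
                    break
            if want_nonsyn:
                nonsyn += 1
            else:
                syn += 1
        pid = f"pair{i + 1:03d}"
        pairs.append(CodonAlignment(pid, "".join(codons), "".join(mutant), label))
        truth.pair_changes[pid] = (syn, nonsyn)
    return pairs, truth
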