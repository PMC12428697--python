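# Methods

This note documents the models, estimators and numerical conventions behind
`panpav`, the design choices made where several reasonable options existed,
and what the synthetic-data generators do and do not emulate.

## Presence calling

Presence is called from breadth of coverage: the fraction of a gene's
positions covered at depth ≥ `min_depth` (default 1 read; no depth floor
beyond "covered" is imposed). A gene is present in a sample iff

    gene_breadth >= t_gene  AND  cds_breadth >= t_cds

with defaults t_gene = t_cds = 0.4. The two thresholds are interpreted as
(gene-body breadth, CDS breadth) combined conjunctively, and boundaries are
inclusive so that a breadth exactly equal to the printed 0.4 parameter
passes. CDS breadth is computed over the *union* of CDS intervals (overlaps
between isoforms collapsed); a gene with an empty CDS union has an
*undefined* CDS breadth (NaN, never silently 0) and is excluded from the
matrix with a logged reason. Coordinates are 0-based half-open internally;
GFF3's 1-based closed convention is converted at the reading boundary.
Presence is monotone in both thresholds by construction: raising either can
only turn 1s into 0s.

## Partitioning and rarefaction

With presence frequency f = count/N over N accessions the bands are:
core f = 1 exactly (count = N, not merely f ≥ 0.99), softcore
[0.99, 1), shell (0.01, 0.99), cloud (0, 0.01]. The conventional verbal
bands ("99–100%", "1–99%", "0–1%") overlap at their endpoints; the
half-open assignment above makes them disjoint, keeps "≤ 1%" for cloud,
and reserves core for genes present in *every* accession. Genes absent
from every sample — possible after thresholded calling — are reported
separately as "absent everywhere" and excluded from class percentages.
Percentages are rounded half-up at two decimals, the convention of printed
tables; note that published tables rounded this way are occasionally off
by one unit in the last digit, which is a property of the source tables,
not of the arithmetic here.

Rarefaction draws, per replicate (default R = 100), one uniform random
permutation of the samples and accumulates the gene union (pan) and
intersection (core) along its prefixes. A length-k prefix of a uniform
permutation is a uniform k-subset without replacement, so each subset size
has the correct marginal distribution, while the coupling across k makes
the replicate means exactly monotone (pan non-decreasing, core
non-increasing) for every seed — matching the curve's defining invariants
rather than only their expectation. At k = N both curves hit their exact
full-sample values in every replicate.

Growth models follow standard microbial pan-genome practice (no specific
family is canonical for plant PAV data): pan size is fitted to the power
law P(k) = A·k^B + C and core size to exponential decay
C(k) = A·e^(−k/τ) + Ω, by unweighted least squares on replicate means
(`scipy.optimize.curve_fit`, tolerances 1e-15, data-driven starting
values). A curve is *saturated* when the fitted marginal gain of the last
added sample is below 0.1% of the fitted level. Non-convergence is
reported with residuals; parameters are never fabricated.

## SNP filtering and Weir–Cockerham FST

Variant filters (all strict inequalities): bi-allelic SNPs only, site
quality > 10, call rate > 0.7, minor-allele frequency > 0.05 computed over
called alleles. Removed sites are tallied against the first rule they
fail, in that order.

Per-site FST uses the Weir & Cockerham (1984) variance components for
r = 2 populations, with per-site sample sizes n_i equal to the called
diploid counts (missing genotypes excluded per site):

    n̄  = (n₁+n₂)/2,   n_c = (2n̄ − Σn_i²/(2n̄))/(r−1)
    p̄  = Σn_i·p_i/(2n̄),  s² = Σn_i(p_i−p̄)²/((r−1)n̄),  h̄ = Σn_i·h_i/(2n̄)
    a = (n̄/n_c)(s² − [p̄(1−p̄) − s²(r−1)/r − h̄/4]/(n̄−1))
    b = (n̄/(n̄−1))(p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄))
    c = h̄/2,   θ = a/(a+b+c)

θ is undefined (NaN) at sites monomorphic across both populations or with
n̄ ≤ 1. Windowed FST is the "weighted" ratio of sums Σa/Σ(a+b+c) over a
window's defined sites — not the mean of per-site ratios — which is
invariant to site order and robust to low-information sites. Windows are
100 kb non-overlapping by default (size and step configurable; the window
scheme is a choice, as is ranking windows rather than single sites);
windows with fewer than 5 defined sites are dropped.

## Composite-likelihood sweep score

A deliberately simple, fully deterministic stand-in for cross-population
CLR scans (the interface also accepts external per-window score files, so
a real XP-CLR run can be dropped in). Under neutral drift the object
population's frequency p_obj at a site is modelled as Normal(p_ref,
ω·p_ref(1−p_ref)) truncated to [0,1] and renormalised; ω̂ is the
genome-wide mean of (p_obj−p_ref)²/(p_ref(1−p_ref)) over sites with
reference frequency in (0.05, 0.95), requiring ≥ 50 such sites. The
per-site log-likelihood integrates the Binomial(n_obj, p) sampling of the
observed allele count over this kernel by fixed 64-node Gauss–Legendre
quadrature on [0,1]. Per window the score is

    2·( max_λ Σ log L(λ·ω̂) − Σ log L(ω̂) ),  λ ∈ {1, 1.5, 2, 5, 10, 20, 50}

Because λ = 1 is in the grid, scores are non-negative; a sweep inflates
local differentiation, favouring λ > 1. Unlike published XP-CLR this model
has no recombination distances and no selection-coefficient grid — it is a
rank statistic for windows, sufficient for top-decile interval recovery,
not an estimator of selection strength.

Selection intervals: the ceil(0.10·W) highest-scoring windows per track
(ties broken by score, then chromosome, then start), merged into regions
per track, intersected between tracks, and merged again so no two
intervals overlap or abut. Genes overlap an interval by ≥ 1 bp under
half-open semantics; a gene abutting an interval end is excluded.

## Distances, trees, PCA

SNP distance is the allele-sharing p-distance: per shared called site half
the number of allele differences between diploid genotypes (0, 0.5, 1),
averaged over sites; pairs sharing fewer than 50 called sites are an
error, not a silent 0. PAV distance is Jaccard on present-gene sets
(two empty sets → 0, empty vs non-empty → 1), with Hamming as an
alternative.

Trees are built by Saitou–Nei neighbor joining from either distance type
(the field's external minimum-evolution and maximum-likelihood tree tools
are replaced by one deterministic in-package algorithm whose newick output
stays viewer-compatible). Ties in the Q criterion are broken by the
smaller (i, j) index pair, making output independent of floating-point
argmin vagaries; negative branch lengths are retained and flagged rather
than clamped, preserving the information that the metric was non-additive
there. On additive inputs NJ is consistent: it reproduces the generating
tree exactly, which the tests exercise against random additive metrics and
against an independent NJ implementation.

PCA is an SVD of the column-centred (optionally unit-scaled) sample ×
feature matrix; coordinates are U·S, variance-explained fractions are
squared singular values over their total, and component rows are
orthonormal. Missing genotypes are mean-imputed per site before SNP PCA;
zero-variance features are dropped (logged) only under scaling.

## NG86 Ka/Ks

Synonymous sites per codon are counted as the fraction of the three
possible changes at each position that are synonymous (changes creating a
stop count as nonsynonymous), averaged between the two sequences, so
S̄ + N̄ = 3 × codons exactly. Codons differing at k positions average
their synonymous/nonsynonymous difference counts over all k! single-step
substitution orderings, excluding orderings that pass through a stop
codon; in the rare case that every ordering hits a stop, all orderings are
used (steps into or out of stops counted nonsynonymous) and the pair is
flagged. pS = Sd/S̄ and pN = Nd/N̄ are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 leaves the rate undefined (saturation
flag) and the pair excluded from ratio tallies, as is any pair with
Ks = 0. Input pairs must be gap-free, length-divisible-by-3, stop-free
ACGT sequences; homolog detection and alignment are out of scope — pairs
come from input files or the simulator.

The class contrast counts pairs with ratio > 1 and < 1 per class
(undefined and exactly-1 ratios tallied separately, entering neither the
table nor its margins) and applies Pearson's chi-squared without
continuity correction, 1 df. Percentages of >1 pairs are reported against
all pairs of the class. An expected cell below 1 triggers a warning
recommending an exact test; the statistic is still reported.

## Non-reference contig filtering

Per contig, alignment intervals are merged on contig coordinates and the
overlap rate is merged covered bases / contig length — alignment identity
is not considered, and coverage (not identity) is the recorded reading of
the 80% rule. Keep iff length > 500 bp and overlap < 0.80, both strict
per the rule's wording ("greater than", "less than"); removal reasons are
exclusive with `too_short` checked first, making reports
order-deterministic and the filter idempotent on its kept output. Contigs
classified by an upstream similarity search as mitochondrial or
chloroplast are removed as `organelle`, non-plant hits as `contaminant`;
unclassified contigs are kept. Repeat summaries report per-family and
total masked percentages of the full non-reference length, half-up at two
decimals.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of configuration + seed (one
`numpy.random.Generator` passed explicitly, no global state).

**PAV matrices.** Defaults: 109 accessions and 1000 genes split
719/61/208/12 across core/softcore/shell/cloud — the class proportions of
a ~32k-gene plant pan-genome at 1/32 scale, against the accession count
such studies use. Each gene draws a presence frequency uniformly inside
its class's bounds (bounds nest strictly inside the partition bands) and
realises it as a presence count rounded and clamped into the band's
attainable integer range; carriers are chosen uniformly. The clamping
guarantees that every realised frequency classifies back into its own
band — a per-sample Bernoulli draw would breach band edges with positive
probability and make exact class-recovery tests ill-posed. Consequence:
the generator encodes no sample structure in the PAV matrix (carriers are
exchangeable), so PAV-based trees and PCA on it show no population signal;
sample structure lives in the genotype generator.

**Coverage.** A latent per-cell mean is drawn from a Beta centred on the
present (0.95) or absent (0.05) breadth mean with concentration κ = 50,
and gene-body and CDS breadths are drawn around the shared latent —
positively correlated, with the configured marginal means. Breadth is
simulated directly rather than via reads: presence calling consumes
breadth, so read-level simulation would add nothing the tests could see.
Real-data features *not* emulated: mappability artefacts, GC bias,
paralog cross-mapping, depth–breadth coupling. Passing round-trip tests
therefore show the calling rule is implemented correctly, not that 0.4/0.4
is optimal for any real library.

**Genotypes.** Balding–Nichols: per site an ancestral frequency uniform
in (0.05, 0.95); each population's frequency Beta-distributed with mean p
and variance F·p(1−p) (default F = 0.2, four populations of 30/30/25/24
samples, 20k sites on one 20 Mb chromosome); genotypes Binomial(2, p_k).
The model is standard and has closed-form moments, which is what makes
oracle tests possible (for two populations the large-n windowed FST
converges to Σs²/Σ(p̄(1−p̄)+s²/2) computed from the true frequencies).
Sweeps are deterministic frequency displacements
p′ = p + intensity·(round(p) − p) toward the nearer boundary within a
region of the target population — desk-scale and sufficient to test
rank-based interval recovery, but with no linkage disequilibrium, no
allele-frequency trajectory, and no hitchhiking structure. Sites are
unlinked; demographic history beyond per-population F is not modelled.

**Codon pairs.** A random stop-free coding sequence accumulates
single-base changes one at a time; each change is nonsynonymous with
probability ω·N̄/(ω·N̄+S̄), where S̄, N̄ are the starting sequence's NG86
site counts — i.e. the per-site nonsynonymous rate is ω times the
per-site synonymous rate, so the realised Ka/Ks tracks the target ω
(defaults: 50 pairs, 300 codons, 30 mutations). A codon offering no
change of the requested type is resampled; changes are never mislabelled,
and stops are never created. Multiple hits on one codon are allowed, so
NG86's pathwise averaging is genuinely exercised; no transition/
transversion bias or codon-usage bias is modelled.

## Numerical conventions and degenerate inputs

* Percentages: decimal half-up at 2 decimals (`decimal.Decimal`), because
  binary-float round-half-even changes printed table digits.
* Monomorphic FST sites, pairs with undefined ratios, windows with too few
  sites: excluded with explicit NaN/flags/tallies, never coerced to 0.
* Empty matrices, < 2 samples, < 3 taxa, invalid drift or intensity
  parameters: rejected with messages, not warnings.
* Quadrature and λ-grid for the sweep score are fixed, so scans are
  bit-reproducible across runs on equal input.
* Problem sizes in the analysis drivers and acceptance script (1000 genes
  × 109 samples; 20k sites; 50 codon pairs; 3 replicate panels) are chosen
  as the smallest scales at which the recovery properties are stable
  across seeds, keeping every driver in the seconds range on one CPU.

## Known limitations

* The sweep score ranks windows; its magnitude is not comparable to
  published XP-CLR scores (use the external-file loader for that).
* NG86 underestimates divergence at high saturation and ignores ts/tv
  bias; pairs at pS or pN ≥ 3/4 are reported as saturated, not corrected
  by a different model.
* The rarefaction fit families are descriptive; the saturated flag is a
  statement about the fitted curve's tail slope, not a formal test of
  pan-genome openness.
* `filter_variants` treats quality as a site property (VCF QUAL); per-
  genotype qualities are not modelled.
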