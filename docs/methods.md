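# Methods

## Model and assumptions

The core quantity is a per-cell, per-window z-score of read positions.
Each stranded genomic window (fixed-size bin, default 5 kb; or a gene body
in gene mode) is treated independently. Read positions observed anywhere
in the window, pooled over all cells, are reduced to ranks 1..P in
coordinate order with no gaps; rank arithmetic deliberately ignores the
physical spacing of positions, which makes the score invariant to
coordinate shifts and insensitive to window placement. With m_ir the read
count of cell i at rank r, N the window total and N_i the cell total:

    mu    = (1/N) sum_ir r m_ir
    sigma = sqrt((1/N) sum_ir m_ir (r - mu)^2)        (population denominator)
    z_i   = (1/N_i) sum_r m_ir (r - mu)/sigma

The null model is exchangeability: every cell draws its read positions
from the same distribution. Under it E[z_i] = 0, and treating a cell's
ranks as independent draws gives Var(z_i) ~ 1/N_i, so z*sqrt(N_i) is
approximately standard normal. The approximation ignores (a) the
dependence induced by estimating mu and sigma from the same data — an
O(N_i/N) shrinkage, negligible when no cell dominates the window — and
(b) rank dependence within a cell. The identity sum_i N_i z_i = 0 is
exact and is used as a numerical self-check.

Ranks ascend with genomic coordinate on both strands. Biological
orientation (5'→3') is restored only where it matters — the pseudotime
correlation sign is multiplied by −1 on minus-strand windows — so the
score itself stays a pure function of the counts table.

### Read filtering and deduplication

Only uniquely mapping, ungapped, full-length alignments enter the counts
table: CIGAR exactly `<query length>M` and MAPQ ≥ 255 (the STAR
unique-mapper value; configurable for other aligners). This excludes
spliced reads by construction. UMI deduplication keeps one read per
(cell, UMI) when all its copies agree on (chrom, strand, position) and
discards the whole UMI when copies disagree — ambiguity is treated as
contamination rather than resolved by majority. Deduplication is scoped
per cell; plate-format data (one file per cell, no UMIs) can skip it. A
read is anchored at its leftmost aligned base; since only full-match
CIGARs survive, any other fixed anchor would shift every read equally and
leave all ranks unchanged.

## Cell-type test

Per window, cells are grouped by ontology. A (window, ontology) group is
eligible with ≥ min_cells cells (default 20) each having ≥ min_counts
reads (default 10); a window is testable with ≥ 2 eligible groups.
Shallower libraries warrant 10 cells × 5 counts. All reads still
participate in ranking — eligibility filters act only at the median stage,
so the score never depends on metadata.

The statistic is the precision-weighted dispersion of group medians,
T = sum_i (n_i/s2_i)(theta_i - theta_bar)^2 with theta_bar the weighted
mean of medians. Its permutation null is asymptotically chi-squared(I−1),
which is used as a cheap prefilter: only windows with p_chi < 0.05 receive
a permutation p-value (J = 100 label permutations over the frozen
eligible-cell set, medians and variances recomputed from scratch each
time, zero-variance permutations redrawn and counted), reported two-sided
as p_perm = 2 min(cdf, 1−cdf). Benjamini-Hochberg runs across the windows
that received a p_perm; prefiltered windows carry p_chi but no q. A
strict mode instead substitutes p_chi for screened-out windows into the
BH pool — statistically more conservative, exposed as a flag. The
permutation rejection rate under a simulated null sits near 2.5–3%
rather than 5%: the two-sided doubling on an upper-tail-screened
statistic is conservative, which we accept as inherited behaviour.
Effect size is the range (max − min) of group medians, used for ranking
hits, not for inference.

## Pseudotime correlation

Per window (optionally per cell type), Spearman correlation between z and
pseudotime over cells with ≥ 5 reads; a window is tested only with ≥ 300
such cells. P-values use the standard large-n t-approximation; below 30
cells a seeded permutation p-value (9999 resamples) replaces it. The
Bonferroni factor is the number of (window, stratum) tests actually
performed in the run. Significance: |rho| > 0.3 (deep mammalian
trajectories; 0.1 suits shallower data) and corrected p < 0.05. Among
significant windows overlapping an annotated 3'UTR at ≥ 25 %, the
sign-corrected rho classifies the drift: negative = shortening, positive
= lengthening. An optional pseudotime sub-interval restriction (e.g. the
earliest quarter) resolves fine-scale regulation that washes out over a
full trajectory.

## Peak calling

Read positions of a significant window (every read one observation,
whole dataset pooled) are fitted with univariate Gaussian mixtures for
k = 1..k_max (default 10). Model selection uses the integrated
complete-data likelihood, implemented as the standard entropy-penalised
BIC in a higher-is-better convention: ICL(k) = −BIC(k) − 2·Σ_n H(τ_n),
with τ_n the posterior component responsibilities; ICL(1) = −BIC(1)
exactly. k* is the knee of the ICL curve — the point of maximum
perpendicular distance to the chord joining the curve's endpoints, on
axes normalised to [0,1] (deterministic, parameter-free); a curve that is
flat to within 1e-3 relative change yields k* = 1. After fitting at k*,
components are merged: while any pair has Bhattacharyya distance

    D = 1/4 ln(1/4 (s1²/s2² + s2²/s1² + 2)) + 1/4 (m1-m2)²/(s1²+s2²)

strictly below 0.5, the mixture is refitted from scratch at k−1 (a pair
at exactly 0.5 keeps both peaks). The 0.5 cut encodes the resolution
limit of ~350 bp-insert libraries: peaks within the insert-length smear
are not distinguishable and should not be reported separately. EM runs
with k-means++-style initialisation, 10 restarts, tol 1e-6, max 500
iterations, component SDs floored at 1 bp; fits are seeded and
reproducible. Windows below 20 reads are not fitted.

## Annotation

GFF3 genes (`gene_name`, falling back to `Name`/`ID`) and
three_prime_UTR features (`ID`) are converted to the package-wide 0-based
half-open convention on read. A window is annotated with a gene or 3'UTR
when the overlap covers ≥ 25 % of the *window* (the feature-fraction
variant is a flag); `window_has_gene` is any-overlap, strand-blind.
`num_3UTR_300bp_downstream` counts same-strand 3'UTR end coordinates
(feature end on +, start on −) inside the window shifted 300 bp
downstream, half-open, clamped at zero. Peak positions (component means
rounded to bp) get strand-aware distances to the nearest same-strand
3'UTR end on each side, and a flag for a same-strand gene within 600 bp
downstream. The downstream-distance summary conditions on that flag and
on distance < 2 kb — beyond which intronic internal priming dominates —
and reports 25/50/75 % quantiles plus a binned histogram/CDF table
(default 100 bins).

## Concordance between datasets

Per window shared by two datasets, the cell types with computable medians
in both are ranked by median score, descending, ties broken by ontology
name; each dataset's ranks are re-ranked 1..m over the shared set. The
statistic is chi = sum_j (1/m_j) sum_i |R_ij − R'_ij|. The null permutes
dataset 2's rank vector independently within each window; the p-value is
lower-tail (small chi = concordant) with the +1 finite-sample correction.
When every window has m = 2, each window's null contribution is
Bernoulli(1/2), so the p-value is computed exactly from Binomial(N, 1/2).

## Synthetic data

The generator emulates the features of 3'-biased droplet data the method
relies on, and nothing more: read starts as mixtures of Gaussian peaks
(sd 150 bp by default, standing in for the insert-length smear of ~350 bp
libraries — a separate convolution would add nothing the statistics can
see), sparse per-cell counts (Poisson, mean 15 by default), cell-type- or
pseudotime-dependent peak mixing, UMI duplicates at a configurable rate,
stranded windows, and reads clipped to the window so simulated truth is
exact. Default differential design: peaks at 1500/2500 bp of a 5 kb plus-
strand window, two ontologies at 80/20 vs 20/80 mixing, 30 cells each.
Pseudotime design: cells at t ~ U(0,1) with distal-peak usage
0.2 + 0.6 t. What the generator does not model — ambient RNA, barcode
collisions, sequencing error, expression-level confounding, multi-gene
windows — means passing tests demonstrate statistical correctness of the
method, not robustness to every artefact of real libraries.

## Verification designs and problem sizes

All checks are seeded and run by `scripts/acceptance.py` and
`tests/test_acceptance.py`:

- Score correctness: 100 random counts tables (2–9 cells, ≤ 6 positions)
  against an independent loop-and-dict evaluation of the four equations;
  agreement to 1e-9 and the weighted-sum identity to 1e-9·N.
- Null calibration: 500 exchangeable windows (3 ontologies × 30 cells,
  N_i ~ Poisson(15)+10, 40-position Dirichlet profile): Var(z√N) in
  [0.8, 1.2]; KS normality of z√N at 5000 cells with N_i ≥ 20 (p > 0.01);
  permutation rejection at α = 0.05 within [0.02, 0.09]; permuted-T vs
  chi-squared(3) QQ correlation > 0.95 on a 200-cell window.
- Power: 100 windows of the default differential design; ≥ 90 % must be
  significant at q < 0.05 with the distal-skewed ontology's median higher.
- GMM: Bhattacharyya closed forms (0, exactly 0.5, 0.11157); two-peak
  recovery (Δ = 1000 bp, sd 150, 300 reads) in ≥ 95/100 seeds; peaks
  100 bp apart merging to k = 1. GMM verification runs at 300
  reads/window, k_max = 5, 3 EM restarts, tol 1e-4 — recovery there
  matches the full EM defaults while keeping the whole suite fast.
- Pseudotime: drift 0.2 + 0.6 t over 500 cells recovers rho_signed > 0.3
  with corrected p < 0.05 in ≥ 95/100 seeds; strand flip inverts every
  call; 500 null windows yield ≤ 1/500 + 3·SE false calls.
- Concordance: identical 20-window, 5-ontology profiles give chi = 0 and
  p ≤ 0.001 at J = 5000; a reversed m = 3 profile gives chi = 4/3
  exactly; 200 null seeds give approximately uniform p.
- Annotation: a constructed fixture with 3'UTR ends 286 bp downstream of
  each peak reproduces a median distance of exactly 286; distances agree
  with a naive O(n·m) scan on 50 random fixtures.
- Determinism: simulate + full pipeline twice under one seed produce
  byte-identical TSVs.

## Numerical choices and degenerate inputs

Windows with a single observed position (sigma = 0) are unscorable and
skipped. Groups with zero score variance are dropped from the T statistic
(window untestable if < 2 remain); zero-variance permutations are redrawn
with a bounded budget. Median of an even set is the midpoint. Constant z
or constant pseudotime skips the correlation. Empty inputs yield empty,
well-formed outputs. Overlapping genes in gene mode assign a read to the
gene with the smaller start (then lexicographic id). All coordinates are
0-based half-open internally; GFF3 converts on read/write.

## Known limitations

The score conflates all forms of read-position change — APA, splicing,
intron retention, internal priming — and cannot distinguish them without
annotation; peaks within an insert length of each other are deliberately
merged; multi-gene windows mix signals from different genes (gene mode
mitigates this at the cost of requiring annotation); the chi-squared
prefilter plus two-sided permutation p is conservative under the null;
Spearman's rho underpowers non-monotone pseudotime effects.
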