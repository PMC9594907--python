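# readzs

Annotation-free, single-cell-resolved detection of differential RNA
processing from scRNA-seq read positions.

3'-biased droplet protocols (10x) concentrate reads near transcript ends,
so shifts in *where* a gene's reads fall — alternative polyadenylation,
3'UTR length changes, intron retention, splicing kinetics — leave a
signature in the read-position distribution even when no isoform
annotation exists. This package quantifies that signature per cell and per
stranded genomic window, without peak calling or pseudobulking, and is
aimed at anyone with tagged BAMs and a cell-metadata table: cell-type
differential RNA processing, trajectory (pseudotime) analyses of 3'UTR
length, and cross-dataset reproducibility checks.

## The statistic

Within one stranded window, every genomic position carrying at least one
read (pooled over all cells) gets a rank *r* = 1..*P* in coordinate order,
with no gaps. With *m<sub>ir</sub>* the read count of cell *i* at rank *r*
and *N* the window total:

```
mu    = (1/N) sum_ir r m_ir                   mean rank
sigma = sqrt((1/N) sum_ir m_ir (r - mu)^2)    population SD of ranks
r~    = (r - mu) / sigma                      normalized rank
z_i   = (1/N_i) sum_r m_ir r~                 per-cell score
```

Under the null that cells are exchangeable, E[*z<sub>i</sub>*] = 0 and
Var(*z<sub>i</sub>*) ≈ 1/*N<sub>i</sub>*, so *z√N* is approximately
standard normal; Σ *N<sub>i</sub> z<sub>i</sub>* = 0 holds exactly.
Downstream of the score:

- **Cell-type test** — per window, the precision-weighted dispersion of
  per-ontology medians `T = sum_i (n_i/s2_i)(theta_i - theta_bar)^2` is
  screened against chi-squared(I−1) and, when p < 0.05, assigned a
  two-sided label-permutation p-value; Benjamini-Hochberg across windows.
- **Pseudotime** — Spearman correlation of *z* with pseudotime, Bonferroni
  corrected; the sign, corrected by ×(−1) on minus-strand windows,
  classifies 3'UTR lengthening vs shortening for UTR-overlapping windows.
- **Peaks** — a Gaussian mixture over read positions of significant
  windows, component count from the knee of the ICL curve, components
  closer than Bhattacharyya distance 0.5 merged by refitting.
- **Annotation** — windows and peaks intersected with GFF3 genes/3'UTRs
  (≥25 % overlap), strand-aware distances to the nearest 3'UTR ends.
- **Concordance** — Spearman-footrule statistic over per-window cell-type
  rankings in two datasets, with a within-window permutation null.

## Worked example

Simulate a two-cell-type window (peaks at 1500 and 2500 bp, 80/20 vs 20/80
mixing, 40 cells each, UMI duplicates included), then run the whole
pipeline:

```
readzs simulate --out-dir sim --seed 7 --n-cells 40
readzs all --bam sim/reads.sam --metadata sim/metadata.tsv \
    --gff sim/annotation.gff3 --min-counts 5 --min-cells 10 \
    --seed 3 --out-dir run
```

The run reports `ingest: umi_duplicates_collapsed=114` and
`passed=1276` (1276 pass-filter records collapse to 1162 molecules), then
`test: 1 windows tested, 1 significant`. The result tables:

`run/results.tsv` — the window is called with a large effect:

```
window_id  T       p_chi     p_perm  q    effect_size  n_ontologies  significant
chr1:+:0   374.57  1.89e-83  0.0     0.0  1.015        2             True
```

`run/medians.tsv` — typeA (80 % proximal peak) skews upstream (median z
−0.46), typeB downstream (+0.55); their gap is the effect size above:

```
window_id  ontology  n   median_z  var_z
chr1:+:0   typeA     40  -0.460    0.066
chr1:+:0   typeB     40  +0.555    0.044
```

`run/peaks.tsv` — the mixture recovers both simulated peaks
(truth: 1500 and 2500 bp, sd 150):

```
window_id  peak_index  mean     sd      weight  k_final
chr1:+:0   0           1491.5   144.8   0.504   2
chr1:+:0   1           2504.2   146.1   0.496   2
```

`run/peaks_annotated.tsv` — the distal peak sits 282 bp upstream of the
annotated 3'UTR end (the fixture places the UTR end at 2786), consistent
with the insert-length offset expected from 10x library geometry.

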