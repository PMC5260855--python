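# endosig

Genomic and transcriptomic comparison of converted endothelial-like cells
with primary endothelium: a tested, reusable implementation of the
computational core of such studies — differential transcription-factor
binding from ChIP-seq counts, region-set algebra over the resulting bound
regions, annotation-overlap and known-motif enrichment, transcriptome
distances and differential expression, and low-coverage whole-genome
copy-number segmentation. Every stage has a matched synthetic-data
generator with known ground truth, so the whole pipeline can be exercised
and validated without any sequencing data.

Intended users: computational biologists analysing ChIP-seq binding
purviews across cell states (e.g. reprogrammed vs primary endothelial
cells), and anyone needing a small, fully specified negative-binomial
differential-binding framework with its supporting interval arithmetic.

## The models

**Differential binding.** Region-level ChIP fragment counts $y_{gj}$
(region $g$, sample $j$) are modelled as negative binomial with mean
$\mu_{gj}$ and variance $\mu_{gj} + \phi_g \mu_{gj}^2$, with
$\log \mu_{gj} = x_j^\top \beta_g$ after scaling counts to a fixed
million-read reference library. Per-region dispersions are method-of-moments
estimates shrunk toward a common Cox–Reid adjusted-profile-likelihood value;
contrasts $c^\top \beta_g = 0$ are tested by likelihood ratio against
$\chi^2_1$; p-values are Benjamini–Hochberg adjusted. A region is called
differentially bound (up or down) iff

$$|\log_2\mathrm{FC}| > 1.5 \quad\wedge\quad \mathrm{FDR} < 0.01
\quad\wedge\quad \log_2\mathrm{CPM} > -3 .$$

**Region sets.** Intervals are 0-based half-open; two regions are "shared"
iff they overlap by ≥ 1 bp. On this primitive the package builds Core sets
(regions of one set overlapping every other set), Up/Down sets from the
contrast calls, Unique sets (down-modulated and absent from all exclusion
sets), percent-shared statistics and Venn counts anchored on the merged
union.

**Overlap enrichment.** A query set vs an annotation track is summarised by
the continuity-corrected log-odds ratio
$\ln\frac{(a+\tfrac12)(d+\tfrac12)}{(b+\tfrac12)(c+\tfrac12)}$
where $a/b$ count query regions overlapping/not overlapping the track and
$c/d$ the same for a random control whose intervals all have the query's
median bp length, placed uniformly with chromosomes drawn by length.

**Motif enrichment.** JASPAR-style position weight matrices are scored as
log₂-odds against the background; a sequence is a hit if any window on
either strand reaches 80% of the maximum achievable score. Foreground vs
background hit counts go into a one-sided Fisher exact test;
$E = p \times (\#\text{motifs tested})$ and results are ranked by
$-\log_{10} E$ (inverse log E, higher = more enriched).

**Copy number.** Reads are binned into 10-kb tiles; per-bin ratios are
$\log_2\frac{s\cdot\text{count}_\text{sample}+1}{\text{count}_\text{ref}+1}$
with $s = N_\text{ref}/N_\text{sample}$; ordered ratios are partitioned by
circular binary segmentation (max two-arc t-statistic, permutation p <
0.01), and a segment is a split call iff its mean deviates from the
bin-weighted median of segment means by more than 3 genome-wide ratio
standard deviations.

**Transcriptome.** FPKM matrices are compared with Welch's unequal-variance
two-sided t-test on $\log_2(\mathrm{FPKM}+1)$ plus a $|\log_2\mathrm{FC}| >
1$ cut on averaged FPKMs; sample distances are $1 - r$ (Pearson) on
log-transformed values, clustered with deterministic complete linkage;
heatmap matrices are normalised per transcript by the row maximum.

## Worked example

Simulate a ChIP count matrix with 10% planted differentially bound regions
and call them:

```bash
$ endosig simulate --seed 17 --out-dir demo --n-regions 400
seed=17 wrote demo/chip_counts.tsv (400 regions)
$ endosig diffbind demo/chip_counts.tsv demo/sample_sheet.tsv --out demo/dbr.tsv
33 DBRs called of 400 regions -> demo/dbr.tsv
$ head -3 demo/dbr.tsv
chrom	start	end	logFC	logCPM	p	fdr	call
chr1	158000	158500	-3.035623909	3.984893108	5.345370144e-09	1.644729275e-07	down
chr1	68000	68500	2.780858401	9.272629785	4.075308002e-14	1.630123201e-11	up
```

40 regions carry a true ±2 log₂ fold change; 33 pass the calling criteria
(the remainder fall below the |logFC| > 1.5 cut after shrinkage and
sampling noise), sorted by |logFC| with the strongest effects first.

The transcriptome side, in Python:

```python
from endosig.simulate import simulate_expression
from endosig.expression import (correlation_distance_matrix,
                                hierarchical_cluster,
                                distance_to_reference_average)

expr, truth = simulate_expression(1000, ["mac"]*3 + ["ec"]*3,
                                  de_fraction=0.15, lfc=3.0,
                                  noise_sd=0.3, seed=17)
d = correlation_distance_matrix(expr)          # 1 - Pearson on log2(FPKM+1)
print(hierarchical_cluster(d).to_newick())
print(distance_to_reference_average(expr, ["ec_3", "ec_4", "ec_5"]))
```

prints a dendrogram whose first split separates the two cell populations
and per-sample distances to the average reference profile:

```
((mac_0:0.0088,(mac_1:0.0083,mac_2:0.0083):0.0005):0.0630,
 (ec_3:0.0114,(ec_4:0.0104,ec_5:0.0104):0.0010):0.0604);
mac_0    0.1333   mac_1    0.1346   mac_2    0.1339
ec_3     0.0077   ec_4     0.0069   ec_5     0.0073
```

— the non-reference samples sit ~0.13 correlation-distance units from the
average reference sample, the reference replicates essentially at 0.

`endosig run --seed 17 --out-dir run/` executes every stage end to end on
synthetic inputs and writes all artifacts plus the resolved configuration;
identical seed and configuration reproduce every output byte for byte.

## Layout

- `src/endosig/intervals.py`, `region_sets.py` — interval primitives, set algebra
- `src/endosig/diffbind.py` — NB dispersion/GLM/contrast/FDR/DBR calling
- `src/endosig/overlap.py` — matched controls, log-odds enrichment, derived chromatin maps
- `src/endosig/motifs.py` — PWM scanning, Fisher enrichment, accessory-motif search
- `src/endosig/cnv.py` — binning, ratio normalisation, CBS, split calling
- `src/endosig/expression.py` — DE genes, distances, clustering, heatmap scaling
- `src/endosig/simulate.py` — ground-truth generators for every stage
- `src/endosig/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI

See `docs/methods.md` for the statistical methods, default parameters and
their rationale, and known limitations.
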