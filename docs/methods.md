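# Methods

This note records the statistical models the package implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Negative-binomial differential binding

### Model

Counts $y_{gj}$ for candidate region $g$ in sample $j$ follow
NB$(\mu_{gj}, \phi_g)$ with variance $\mu + \phi\mu^2$ and log link
$\log\mu_{gj} = x_j^\top\beta_g + o_j$. Candidate regions are an input: the
framework makes no attempt to derive them from alignments.

### Library-size handling

The default pipeline scales counts to a fixed reference library of
$10^6$ reads ($z_{gj} = y_{gj}\cdot 10^6/N_j$, i.e. the CPM scale) and fits
the NB model to these pseudo-counts with zero offsets. Using a *fixed*
reference — rather than, say, the mean observed library — makes every
downstream statistic an exact function of count/library ratios, so scaling
any sample's library and counts together provably changes nothing. The
classical alternative, raw counts with $o_j = \log N_j$ offsets, is fully
implemented (`fit_nb_glm(..., offsets=...)`,
`differential_binding(normalization="offsets")`); it is not the default
because an offset-GLM maximum-likelihood fit re-weights a sample whose
exposure changes, so exact invariance under joint count/library scaling
cannot hold there (the residual weight $1/(1+\phi\mu)$ changes with
$\mu$). With equal library sizes the two modes coincide.

### Dispersion estimation

- Per-region *moment* estimate: within each group of the chosen design
  factor(s), $\hat\phi$ solves $v = m + \phi m^2$ from the group sample
  mean and unbiased variance of normalised counts; groups pool with
  degree-of-freedom weights; negative solutions truncate to 0.
- *Common* value: a single $\phi$ maximising the Cox–Reid adjusted profile
  likelihood over all regions (group means profiled out, likelihood
  penalised by $\tfrac12\log\det X^\top W X$). A common value anchored on
  the per-region moment distribution instead (e.g. its positive median) is
  biased low at 2×3 designs — the moment distribution is strongly
  right-skewed at 4 residual df — and a low anchor makes the
  likelihood-ratio null anticonservative; the adjusted profile likelihood
  recovers the simulation truth to a few percent.
- *Tagwise* (used for fitting):
  $\hat\phi_g^{tag} = (d\,\hat\phi_g^{mom} + d_0\,\hat\phi^{com})/(d+d_0)$
  with $d$ the residual df and prior weight $d_0 = 10$. All-zero regions
  take the common value and are flagged.

### Fitting and testing

Fisher scoring, batched across regions (all regions share the design
matrix), to a maximum-score tolerance of $10^{-8}$ or 100 iterations, with
per-region step-halving when a step would decrease the likelihood;
non-converged regions are flagged, never silently dropped. Contrasts are
tested by likelihood ratio: the null model is refitted on a null-space
basis of $c^\top$ and $2\Delta\ell$ is referred to $\chi^2_1$. The LRT was
preferred over Wald because it behaves better at low counts. Abundance is
$\log_2(\overline{\mathrm{CPM}} + 0.5)$.

### FDR and calling

Benjamini–Hochberg step-up (via statsmodels), clipped to 1. Calls use
strict inequalities at $|\log_2FC| > 1.5$, $\mathrm{FDR} < 0.01$,
$\log_2\mathrm{CPM} > -3$; output is ranked by $|\log_2FC|$ descending,
ties by FDR ascending.

### Measured operating characteristics (from `scripts/acceptance.py`)

At 5,000 regions, two groups × 3 replicates, $\phi = 0.1$, equal
million-read libraries: the full-null raw-p fraction below 0.05 is ≈ 0.057
with zero regions passing the calling criteria; planting $|\log_2FC| = 2$
in 10% of regions gives sensitivity ≈ 0.87–0.89 with an observed
false-discovery proportion below 0.01.

## Region-set algebra

- "Shared" = ≥ 1 bp overlap between 0-based half-open intervals; no
  reciprocal-fraction requirement (none is standard for site-level
  sharing).
- `RegionSet.merge` joins strictly overlapping intervals only; abutting
  intervals remain separate (they are distinct sites). The base-pair
  `union`/`subtract` operations, used for derived chromatin maps, do
  coalesce abutting coverage because there they describe covered bases.
- Venn counts are anchored on the merged union of all input sets: each
  union interval gets the signature of inputs it overlaps. Anchoring is
  required for well-defined counts when sets fragment each other.
- Percent shared is interval-count based ($100\cdot|\{a\in A:
  a\ \text{overlaps}\ B\}|/|A|$), matching "sites" semantics; it is
  deliberately asymmetric.

## Overlap enrichment

- The matched control draws every interval at the query's *median* length
  (rounded to an integer), chromosome proportional to its length, start
  uniform over positions where the interval fits. Sampling lengths from
  the query's empirical distribution is available (`match="sample"`).
- The log-odds ratio adds 0.5 to all four cells so it is always finite.
  Natural log by default; log₂ selectable.
- A sensible control size is $\max(10\,|query|, 10^4)$; the helper
  `cross_track_overlap` shares one control across query sets so their
  log-odds are directly comparable.
- Derived chromatin maps (composite / focal-unique / focal-excluded) are
  computed per element-type label independently, as base-pair unions and
  differences.
- Human-to-mouse mapped annotation tracks are consumed as precomputed BED;
  no liftover is implemented.

## Motif enrichment

- PWM scores are $\sum_k \log_2(p_{k,b}/q_b)$; N bases contribute 0. A hit
  requires ≥ 80% of the maximum achievable score (configurable); both
  strands are scanned and minus-strand hits are reported at their
  forward-strand position.
- Counting is sequence-level (≥ 1 hit) rather than occurrence-level:
  robust to hit clustering. Occurrence positions are still available from
  `scan_pwm`.
- Enrichment: one-sided Fisher exact on (hit/no-hit × fg/bg);
  $E = p \times \#\text{PWMs}$ (Bonferroni-style E-value semantics);
  $-\log_{10}\max(E, 10^{-300})$ keeps the report finite.
- Accessory search: foreground = ±50 bp (default) around each sequence's
  best primary hit; background = same-width windows at seeded random
  positions, preferring windows disjoint from the hit window and falling
  back to windows merely not anchored on a hit when the sequence is too
  short for full avoidance. A candidate equal to the primary is reported
  but flagged `self_match`.
- JASPAR PFM counts are normalised per position with a +0.25 pseudo-weight
  per cell. The built-in `example_pwms()` panel (Ets-like GGAA core,
  CCAAT-box, Sox consensus) is synthetic, built from textbook consensus
  sequences at 0.85 per-position identity — intended for simulation and
  testing, not as a database substitute.

## Copy-number segmentation

- Binning: half-open fixed-width tiles (default 10 kb), read assigned by
  $\lfloor pos/width \rfloor$.
- Ratios: sample counts scaled by $N_{ref}/N_{sample}$, +1 added to both
  scaled sample and reference counts, then log₂. Bins at zero in both
  profiles are retained (ratio 0), not masked. No GC or mappability
  correction is applied.
- CBS: for each segment, the two-arc t-statistic (pooled variance) is
  maximised over all circular splits; arcs ending at the segment boundary
  are enumerated once (pair $(i, n)$ duplicates $(0, i)$), making the
  argmax canonical with lexicographic tie-breaking. The split is accepted
  iff its within-segment permutation p (default 1,000 shuffles) is below
  α = 0.01, recursing until no split is accepted. Minimum arc width 2
  bins. The permutation loop runs in a numba kernel (pure-numpy fallback)
  and stops early once enough exceedances guarantee p ≥ α; the full
  permutation stream is always generated, so early stopping never changes
  the random state or the result.
- Split calls: a segment is called iff
  $|\bar r_{seg} - \mathrm{median}_w(\bar r)| > 3\,\hat\sigma$ (strict),
  where $\mathrm{median}_w$ is the bin-weighted median of segment means
  (a robust euploid baseline) and $\hat\sigma$ the genome-wide per-bin
  ratio standard deviation. Both baseline and scale are configurable;
  bin-level σ was chosen over segment-level because the printed rule
  references the ratio noise, and segment-level σ is undefined for
  single-segment genomes.
- Measured characteristics: a planted +1.0 shift over 100 of 300 bins at
  ratio noise σ = 0.2 is recovered with both boundaries within ±2 bins in
  ≈ 100% of seeds; flat null profiles produce zero split calls in
  ≈ 100% of seeds; split locations on arrays ≤ 30 bins equal an
  exhaustive search exactly.

## Transcriptome procedures

- A pseudocount of 1 precedes every log₂ (fold change, t-test, distances);
  zero FPKMs are common and the transform must be total.
- The Welch test runs on $\log_2(\mathrm{FPKM}+1)$ by default (FPKM noise
  is multiplicative); `test_scale="raw"` is available since the choice of
  scale is a judgement call. DE = $|\log_2FC| > 1$ (on averaged FPKMs,
  pseudocounted) AND $p < 0.05$, both strict.
- Clustering is hand-rolled agglomeration (complete linkage default;
  single/average available) so that tie-breaking is fully deterministic:
  among equally close pairs, the lowest sorted cluster ids merge first.
  scipy's implementation serves as an independent oracle in the tests on
  tie-free data. Zero-variance samples yield undefined correlations and
  are reported as missing with a warning; clustering refuses missing
  distances.
- Distance to a reference average: per-gene mean of the reference samples
  on the log scale, then $1 - r$ per sample.
- Heatmap scaling divides each row by its maximum; an all-zero row maps to
  zeros (the only value consistent with "0 to max" colouring).
- Restricted analyses (e.g. clustering on an angiogenesis gene set) take
  the gene list as plain input; no ontology lookup is performed.

## Synthetic-data generators

Every generator is a pure function of its arguments including the seed;
identical calls reproduce outputs bitwise, and each returns a `SimTruth`
echoing the request and the per-unit truth labels (TSV round-trip safe).

- **ChIP counts**: log-normal baseline region means (median 100), exactly
  $\mathrm{round}(n\cdot f)$ regions carry $|\log_2FC| = $ `lfc` with
  random sign between two groups, library-size imbalance acts
  multiplicatively on the mean (not by thinning), counts drawn
  NB($\mu$, $\phi$) (Poisson at $\phi = 0$).
- **Expression**: per-gene log₂ baselines N(5, 2), DE genes shifted by
  `lfc` in the second group, Gaussian log-scale noise, FPKM $= 2^x \ge 0$.
- **Binned coverage**: reference Poisson(depth); sample
  Poisson(depth·2^(shift+ε)), ε ~ N(0, noise_sd) per bin. A direct
  Gaussian log₂-ratio generator (`simulate_log2_ratio_profile`) provides
  the idealised segmentation input with exactly specified ratio noise.
- **Sequences**: i.i.d. bases from the background composition; a selected
  sequence receives one occurrence sampled column-wise from the PWM at a
  uniform position and strand, recorded exactly; occurrences never overlap
  (one per sequence).

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: GC and mappability bias, read-level error
structure, correlated regions/genes, peak-shape effects, overdispersion
heterogeneity beyond the NB tagwise model, repeat structure or
composition heterogeneity in sequences, and diploid genotype structure.

## Problem sizes and determinism

Simulation-based checks use 5,000 regions for the binding framework,
300-bin profiles × 100 seeds for segmentation, 200+200 sequences × 100
seeds for motif ranking, and 500-gene matrices × 100 seeds for clustering
recovery — sizes at which every recovery statistic is stable to well
under its assertion margin. The default seed is 17; every CLI run logs its
seed, and rerunning any pipeline configuration with the same seed
reproduces all outputs byte for byte.

## Known limitations

- Candidate regions, FPKM values, gene lists and mapped annotation tracks
  are inputs; peak calling, expression quantification, GO analysis and
  liftover are out of scope.
- The NB framework assumes a shared design matrix across regions and a
  single factor contrast per run; covariate-rich designs fit through the
  lower-level API.
- CPM-scale pseudo-count fitting slightly misstates the NB variance when
  library sizes are very unequal (the classical trade-off of
  normalised-count NB fitting); the offsets mode is exact in the model but
  not invariant under count/library rescaling.
- The permutation test makes CBS O(segments × permutations × n²); genomes
  are processed per chromosome, which is ample for binned low-coverage
  data but not for per-base signals.
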