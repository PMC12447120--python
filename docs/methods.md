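# Methods

`kmerquant` implements an alignment-free bulk RNA-seq analysis: gene
expression is quantified by counting *gene-specific unique gapped
k-mers*, summarized by trimmed means, normalized between samples by a
quantile-curve offset, and tested for differential expression with
Welch t-tests and Benjamini–Hochberg FDR control. A ground-truth read
simulator exercises the whole chain. This note records the model, its
assumptions, the tunable constants, and the design choices made where
the design was genuinely open.

## Gapped k-mers and the spaced seed

A gapped (spaced-seed) k-mer samples `k` *considered* positions from a
window of length `w`; *ignored* positions are skipped, so a read base
that disagrees with the reference at an ignored position still produces
the same k-mer — the seed tolerates scattered mismatches without any
alignment. The default seed is

```
######_##_###___#___###_##_######     (w = 33, k = 23, 10 ignored)
```

It is palindromic (equal to its own reversal), which makes canonical
counting well defined: for a palindromic mask, masking the reverse
complement of a window equals reverse-complementing the masked k-mer,
so `min(forward, reverse-complement)` is a strand-free representative.
Counting is canonical by default because RNA-seq library strandedness
varies between protocols and a strand-agnostic count is correct for
both; a stranded mode (forward-strand k-mers only) is available where
the protocol is known. Windows containing a non-ACGT base at a
considered position are skipped whole — no partial credit, matching
standard k-mer-counter behavior. Input sequence is uppercased;
soft-masked (lowercase) regions are *not* excluded, because the
uniqueness filter below subsumes repeat masking. All coordinates are
0-based, half-open internally; GFF3 (1-based, closed) is converted on
read and written back losslessly.

## The unique-k-mer index

A k-mer quantifies a gene only if it is *specific* to it: every genomic
window producing that (canonical) k-mer must lie entirely within the
one gene's annotated span. Specificity is resolved at the genomic gene
span (introns included) — the genome, not a transcriptome, is indexed,
so no splicing model is needed and intronic signal is accepted as part
of the gene. Three consequences of the strict reading:

* an occurrence in intergenic sequence disqualifies the k-mer;
* occurrences inside two *overlapping* genes disqualify it (assigned to
  neither);
* multiple occurrences inside the *same* gene are allowed; the
  multiplicity is recorded in the index, and summarization uses raw
  per-k-mer counts without dividing by it (the recorded value permits
  an optional correction downstream).

The builder is a two-pass vectorized scan (window census, then
containment labelling) whose result is independent of chunking order;
on genomes up to tens of kilobases it is verified exactly against an
exhaustive brute-force enumeration plus containment filter. The index
serializes as a sorted TSV with a header recording mask, strand mode
and input digests, so builds are byte-reproducible.

## Quantification

Each read is scanned window by window; every indexed (canonical) masked
k-mer increments its gene's count for that k-mer. Counting is per
window, not per read: a k-mer recurring within one read counts each
occurrence. Read qualities are ignored (inputs are assumed
quality-controlled upstream); paired-end mates are treated as
independent single reads. Counting is exactly order-invariant and, in
canonical mode, invariant to reverse-complementing any read.

Per gene and sample, the per-k-mer counts are collapsed to one value by
a symmetric trimmed mean over the gene's *entire* indexed k-mer set —
k-mers with zero reads contribute zeros — so the denominator is a fixed
property of the gene and values are comparable across samples. The trim
fraction removes `floor(f·n)` values from each tail; the default
`f = 0.05` trims mildly enough that short genes' profiles are not
hollowed out while still discarding outlier k-mers (e.g. ones hit by a
recurrent sequencing-error artifact). Ties at the trim boundary are cut
by stable sorted position. Genes with no indexed k-mer at all are
*absent* (`NA` in every output), never zero.

## Between-sample normalization

Sequencing depth differs between samples approximately multiplicatively
— a single additive offset in log space. Per sample, the quantiles of
`log2(expression + pseudocount)` over quantifiable genes are evaluated
on a grid from the median to the 0.98-quantile (step 0.01, i.e. 49
points); the per-grid-point mean across samples is the *average
quantile curve*; each sample's offset is the intercept-only regression
of its curve onto the average. For least squares the closed form is the
mean difference of the curves over the grid, so fitted offsets always
sum to zero and the offset-shifted curves average exactly to the
average curve. An L1 variant (median difference over the grid, robust
to a few discordant grid points) is selectable; least squares is the
default. The band choice is deliberate: below the median the curve is
dominated by zeros, dropouts and the pseudocount; above the
0.98-quantile a handful of extreme genes could steer the fit.

Zeros are made finite by a pseudocount (default 0.5, configurable,
recorded in output metadata) added before the log2. One exact property
worth knowing: because the average curve includes every sample,
multiplying one sample's raw column by `c` changes its offset by
`−log2(c)·(S−1)/S` (S samples) and translates *every* normalized column
by the common constant `log2(c)/S` — all between-sample structure,
which is what the downstream test consumes, is restored exactly up to
pseudocount curvature.

## Differential expression

Testing operates on the normalized log2 matrix; effect sizes are
reported as fold changes between geometric means. On the linear
(pseudocounted, depth-corrected) scale the geometric mean is
`2^mean(log2 values)`, so the fold change equals `2^(Δ of group mean
log2 values)` and the two views are consistent by construction. The
log scale is used for testing because it stabilizes variance across the
expression range and makes the t-test invariant to the multiplicative
normalization.

Per gene, a two-sample t-test with unequal variances (Welch) with
Welch–Satterthwaite degrees of freedom produces the p-value
(two-sided by default; the analysis defines "up" but sidedness is a
flag). Degenerate genes: both groups constant and equal give `t = 0,
p = 1` (a legitimate non-discovery); both constant and unequal are
*untestable* (no variance information at all), as are absent genes.
Untestable genes are excluded from the Benjamini–Hochberg family size
and labelled, never silently dropped. BH adjustment is the standard
step-up procedure; a gene is called **up** iff `fold_change > 1.61`
*and* `FDR < 0.05`, both strict; **down** mirrors with
`fold_change < 1/1.61`. The 1.61 threshold is treated as an opaque
configurable constant of the analysis. No variance
moderation/shrinkage is applied — the point of the pipeline is the
plain Welch + BH procedure, and its power consequences at three
replicates are characterized below.

## Synthetic data

The simulator emulates exactly the structure the analysis assumes, with
every default chosen once as the package's study conditions:

* **Genome**: i.i.d. uniform ACGT; genes of 500 bp separated by 200 bp
  intergenic spacers on one chromosome. An optional `repeat_spec`
  plants a verbatim segment into several genes and once intergenically,
  guaranteeing the uniqueness filter has real work.
* **Design**: two conditions × 3 replicates; 10% of genes truly
  upregulated at log2FC 2 in the treatment group.
* **Abundance**: per-gene expected read count at depth 1 is log-normal,
  median `2^6 = 64` reads (≈13× coverage of a 500 bp gene), log2-sd 1.
* **Replicate noise**: multiplicative log-normal, sd 0.2 in log2 units
  (≈15% CV), applied to the expected count and rounded. The value is
  calibrated to the procedure it feeds: a Monte-Carlo ceiling for plain
  Welch + BH at n = 3 and log2FC 2 gives ~0.86 sensitivity at sd 0.2
  but only ~0.46 at sd 0.3, so 0.2 represents the well-controlled
  cell-culture replicates this analysis is designed for while leaving
  the test's 0.7 sensitivity floor attainable; negative-binomial
  read-level noise is deliberately not modelled, since the t-test
  consumes log-scale values and log-normal noise exercises it
  equivalently.
* **Depth**: per-sample multipliers uniform in [0.5, 2], a 4-fold range
  that forces the normalization stage to do real work.
* **Reads**: 100 bp, start positions uniform within the gene span (no
  splicing, matching the gene-span uniqueness model), strand uniform,
  i.i.d. substitution errors at 0.5%, constant quality `I` (qualities
  are ignored downstream).

Everything downstream of a seed is byte-reproducible, and the truth
tables store expected next to realized per-gene counts so failed
recoveries are diagnosable. What the simulator does *not* emulate —
splicing and isoforms, GC and positional bias, duplicates, quality-
score structure, batch effects — bounds what passing tests show about
real data: they validate the computational pipeline and its statistical
behavior under its own model, not robustness to library-preparation
artifacts.

## Numerical and scale choices

* K-mers are 2-bit packed into int64 (A<C<G<T preserves lexicographic
  order, so numeric min = lexicographic min and sorted codes equal
  sorted strings); `k = 23` uses 46 bits.
* Quantiles use linear interpolation of order statistics (numpy
  default); the quantile of the log equals the log of the quantile, so
  curves are computed directly on log values.
* Welch p-values come from the t distribution with fractional df;
  BH uses the step-up form with clipping at 1.
* Batch counting joins reads with a spacer of `w−1` ambiguous bases so
  one vectorized scan covers a whole chunk; since masks start and end
  on considered positions, any window crossing a read boundary is
  invalidated by construction, and results are independent of chunk
  boundaries.
* Problem sizes used by the shipped checks: index-vs-oracle equivalence
  on 20 random genomes of roughly 1–3 kb; quantification accuracy on 30
  genes at ≈205× coverage; recovery on ten 1000-gene experiments;
  null control on ten 300-gene experiments — sizes at which the
  brute-force oracles stay exact and the full study runs comfortably on
  one CPU.

## Known limitations

* Gene-span uniqueness discards k-mers shared between overlapping genes
  and counts intronic reads as gene signal; transcript-level
  quantification is out of scope.
* Genes whose sequence is almost entirely shared (e.g. recent
  paralogs) end up with few or no unique k-mers and become absent; the
  index statistics table flags them.
* Plain Welch at n = 3 has heavy-tailed null statistics (variance is
  estimated from 2 df); BH control holds in the null study, but power
  degrades quickly with replicate noise above ~0.25 log2 sd (see the
  calibration above). Users with noisier designs should add replicates
  rather than trust the defaults.
* The normalization model is a single offset per sample; it corrects
  depth, not composition bias or batch structure.
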