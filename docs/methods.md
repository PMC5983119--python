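# Methods

`skiptic` separates two modes of splicing dysregulation by an RNA-binding
splicing repressor such as TDP-43: **gain of function (GOF)**, which skips
exons that are normally constitutively included ("skiptic" exons, SE), and
**loss of function (LOF)**, which de-represses exons that are normally
constitutively excluded ("cryptic" exons, CE). The pipeline quantifies
splicing from junction counts, tests it between two conditions, classifies
events, integrates protein-RNA crosslink data, predicts the coding
consequence of each skip, and couples splicing to gene-level expression.

## PSI and the event model

Splice events are derived from the annotation by pairwise isoform
comparison (cassette, retained intron, alternative 5'/3' splice site,
alternative first/last exon, mutually exclusive exons) and from junction
evidence alone: a junction pair bracketing an unannotated segment inside an
annotated intron is a cryptic-exon candidate, and an unannotated junction
skipping an annotated constitutive exon is a cassette event even when no
skipping isoform exists in the annotation — this is what makes skiptic
exons visible at all.

For a cassette exon with inclusion junctions \(i_1, i_2\) and exclusion
junction \(e\), the per-sample per cent spliced in is

\[ \mathrm{PSI} = \frac{\bar n_{inc}}{\bar n_{inc} + n_{e}},
   \qquad \bar n_{inc} = \tfrac12 (n_{i_1} + n_{i_2}). \]

The mean of the two inclusion junctions is symmetric and robust to
one-sided mapping loss. A sample is informative for an event only when the
denominator reaches `min_total` (default 10 reads); the floor prevents 0/0
artefacts at low coverage and is configurable. Only uniquely mapped
junction reads are counted — multimappers inflate repeat-region junctions.
Intron retention is quantified as body/(body + junction) with the
intron-body signal length-normalized to junction-equivalent units upstream
of the call.

## Differential splicing

Per event, inclusion evidence \(x_s\) out of total \(n_s\) in sample \(s\)
is modelled as beta-binomial with condition mean \(\mu\) and a single
intra-class correlation \(\rho\) shared across events. \(\rho\) is
estimated by method of moments from the pooled within-condition binomial
dispersion statistic (\(E[\chi^2/df] = 1 + \rho(\bar n - 1)\)), clipped to
\([10^{-6}, 0.5]\). The test is a likelihood-ratio of condition-specific vs
shared \(\mu\) (profile likelihood over \(\mu\) by golden-section search on
the logit scale), referred to \(\chi^2_1\). When either condition has
fewer than two informative replicates the test falls back to Fisher's exact
test on pooled counts, using the standard minimum-likelihood two-sided
convention. FDR is Benjamini-Hochberg over tested events. The signed
z-score \(\mathrm{sign}(\Delta\mathrm{PSI})\cdot\Phi^{-1}(1-p/2)\) makes
results from any test comparable across datasets in concordance plots.

\(\Delta\mathrm{PSI}\) is the difference of replicate-mean PSI
(mutant − reference), matching the thresholding definitions below. Note
that replicate-mean and pooled-count \(\Delta\mathrm{PSI}\) weight samples
differently, so their signs can differ for near-zero effects; they agree
whenever the effect is non-trivial on both scales.

## Event categories

Among FDR-significant events (default FDR < 0.01):

* **skiptic**: WT PSI > 0.95 and \(\Delta\mathrm{PSI} < -0.05\);
* **cryptic**: WT PSI < 0.05 and \(\Delta\mathrm{PSI} > +0.05\);
* **alt_shift**: any other significant event.

WT PSI for thresholding is the mean of per-sample WT PSI. A stricter preset
(`dpsi_min = 0.1`, `skiptic.calls.STRICT_DPSI_MIN`) is exposed because both
definitions are in use for volcano-plot-style displays; neither is treated
as canonical. The exclusion fold change is
\(((1-\mathrm{PSI}_{mut})+c)/((1-\mathrm{PSI}_{wt})+c)\) with pseudocount
\(c = 0.001\) guarding total inclusion.

The permutation control re-runs the full test and category calling under
whole-sample condition-label permutations (sampled without replacement from
the distinct non-identity assignments, seeded) and reports the null
distribution of call counts and the empirical
\(p = (1 + \#\{\text{perm} \ge \text{obs}\})/(n_{perm}+1)\).

## iCLIP integration

Crosslink sites (single-nucleotide BED records) are merged into clusters by
single-linkage with a 15-nt gap and kept at >= 3 total crosslinks. The
source protocol does not fix clustering parameters, so these are this
package's defaults and are exposed in config. Cluster midpoints are
assigned to genomic regions with precedence CDS exon > 3'UTR > 5'UTR >
intron > intergenic across overlapping same-strand isoforms.

Pentamer enrichment counts all 4^5 pentamers in ±20-nt strand-aware windows
around crosslink sites; the null re-places the same number of sites
uniformly within the same genes (controlling gene-level base composition
without modelling it), and \(z = (obs - \mu_{null})/\sigma_{null}\) per
pentamer. Flank motif enrichment tests presence of UGUGUG in the exon body
plus 100 nt of each adjacent intron against a background exon set by
Fisher's exact test.

RNA maps align exons at their acceptor and donor boundaries (100 nt into
the exon, 300 nt into the intron, strand-oriented; positions beyond short
exons are masked), compute per-position cluster-coverage fractions,
smooth with a 15-nt running mean, and mark positions where regulated
coverage exceeds the 95th percentile of equal-size bootstrap resamples of
the background set. Binding overlap uses the exon body plus the
downstream-intron flank, matching where the repressor binds its targets
(within the exon and its downstream intron).

## Consequence prediction

Skipping an internal coding exon removes its CDS overlap: frame is
disrupted iff that length is not a multiple of 3 (a skip removing the start
codon is classed as frameshift — the annotated ORF is lost). The post-skip
transcript is rebuilt and scanned codon-by-codon: a stop upstream of where
the original stop maps is a premature termination codon (PTC), and a PTC
>= 50 nt upstream of the final exon-exon junction predicts
nonsense-mediated decay (canonical last-junction rule; the boundary is
configurable, e.g. 55 nt). A transcript is **damaging/unstable** iff the
skip causes a frameshift or introduces a PTC; in-frame deletions of
functional domains without instability are intentionally out of scope.
Standard translation table only (no selenocysteine/readthrough).

## Expression coupling

Differential expression is a negative-binomial Wald test on
median-of-ratios normalized counts with per-gene method-of-moments
dispersions shrunk (geometric mean) toward a fitted \(\alpha(\mu) = a_0 +
a_1/\mu\) trend. It is a defined, auditable statistic — not a
reimplementation of any published tool — so exact discovery counts from
other software are not comparable targets.

* **SE enrichment**: among significantly downregulated genes (FDR < 0.1,
  log2FC < 0), \(k\) = genes containing a skiptic call; the background rate
  is the skiptic frequency among non-significant genes from the same
  expression deciles, weighted by the downregulated set's decile
  composition ("genes expressed at a similar level" operationalized as
  decile matching); \(p\) is the one-sided upper binomial tail. The same
  is computed for upregulated genes and for non-skiptic cassette exons.
* **Stability × downregulation**: Pearson chi-squared (no continuity
  correction) on {downregulated SE gene vs other SE gene} ×
  {damaging/unstable vs other}.
* **Long-intron trend**: genes ranked by signed expression z ascending,
  disjoint 200-gene bins, per-bin mean ± s.e.m. of per-gene mean intron
  length (mean intron length of the longest isoform; total length is the
  exposed alternative), with Spearman correlation between bin index and
  bin mean as the trend statistic.

## The synthetic-study generator

The generator emulates the deposited two-strain mouse experiment: two-group
(4v4) replicated junction counts with opposing GOF/LOF shifts on shared
alternative targets, planted skiptic exons (constitutive in WT, skipped
under GOF), planted cryptic exons (repressed in WT, included under LOF),
UG-repeat motifs and crosslink pileups in skiptic exons and their
downstream introns, negative-binomial gene counts with downregulation
coupled to frame-disrupting skips, and conservation high over skiptic /
low over cryptic exons.

Default conditions: 1700 genes (30 skiptic, 30 cryptic, 20 shared
alternative, 1500 null cassettes, 10 of each remaining class), 4 replicates
per condition, ~100× junction coverage with NB dispersion 0.1, logit-scale
biological PSI s.d. 0.3 (logit-normal jitter keeps PSI in (0,1) and gives
realistic overdispersion), planted |ΔPSI| 0.15 from WT PSI 0.98 (skiptic),
0.01 (cryptic) and 0.5 (shared alternative), 15/48 of skips
frame-disrupting with a 0.5 expression fold change, gene counts NB at mean
500 with dispersion 0.05. Genes are built in transcript orientation and
reverse-complemented onto the genome for minus-strand genes, so motifs and
reading frames are strand-aware by construction; coding sequence is drawn
from non-stop codons with internal CDS exon boundaries codon-aligned, which
makes in-frame skips PTC-free by design and lets the truth table record
frame status exactly.

Per event and sample, total informative reads \(n \sim\) NB(coverage,
dispersion), the sample's inclusion probability is a logit-normal draw
around its condition's true PSI, inclusion reads \(\sim\) Binomial(n, PSI)
are evidenced equally at both inclusion junctions and the remainder at the
exclusion junction — so the PSI estimator above is unbiased by
construction. Cryptic exons are simulated purely as unannotated inclusion
junctions in the junction files, matching how they manifest in real
junction evidence. Everything derives from one seed via independent
substreams per output; the two regimes share the genome/annotation
substream (identical event ids enable the two-way comparison) but use
regime-salted substreams for counts, crosslinks and expression, because
they model separate experiments — sharing count noise would fabricate sign
concordance among null events.

What the generator does **not** emulate: read-level errors and mapping
artefacts, 3' coverage bias, intron-length-dependent junction coverage,
correlated events within a gene, partially-used (leaky) splice sites, and
isoform-level expression structure. Passing tests therefore demonstrate
correctness of the statistics and recovery under the stated noise model,
not performance on aligner output from real tissue.

The conservation track is piecewise-constant in 25-nt segments (per-segment
Gaussian draws, truncated), emitted over exonic sequence only; the track
reader scores unspecified bases as zero and exon means use scored bases
only. Per-base emission genome-wide would be enormous without changing any
per-exon mean comparison.

In long-intron coupling mode the true fold change is a continuous
log-linear function of the gene's standardized log mean intron length
(fc \(= 2^{-\beta z_{len}}\), \(\beta = 0.75\), clipped to [0.25, 4])
rather than a thresholded downregulation probability: a monotone relation
across the whole ranking gives the binned trend its full dynamic range.
Note that with ~10 bins of 200 genes, binning amplifies tiny chance
gene-level correlations (a gene-level Spearman of 0.05 can become a binned
correlation of 0.5), so the coupled/uncoupled contrast is read against the
|ρ| > 0.8 mark rather than against zero.

## Numerical choices and degenerate inputs

* Golden-section profile likelihood: 60 iterations on logit(μ) ∈ [-14, 14];
  the likelihood is unimodal in μ for fixed ρ; LRT statistics are clipped
  at 0.
* p-values are floored at 1e-300 before normal-quantile transforms.
* Events untested in a condition (no informative replicate) are excluded
  from the BH family; all-zero genes are untested in expression.
* Zero-margin 2×2 tables: chi-squared is undefined, proportions are still
  reported. Degenerate Fisher tables (no motif anywhere) report odds ratio
  1, p 1.
* Strand "." junctions are retained for quantification but excluded from
  strand-aware sequence analyses; pentamer analysis skips unstranded sites
  and sites outside genes, with a warning.
* Exons at contig edges have flanks truncated, not errored.

## Problem sizes

The bundled analyses run at the generator's default scale (1700 genes,
~8 junctions each, 4v4 replicates; 2000 events for null calibration; 50
label permutations; 100 pentamer shuffles; 500-1000 RNA-map bootstraps),
which completes the full pipeline in well under five minutes on one CPU
while leaving planted-effect recovery and calibration properties
well-resolved.

## Known limitations

* The beta-binomial LRT relies on χ²(1) asymptotics at 4v4; its measured
  type-I error at p < 0.05 is ~0.05 on null simulations but small-sample
  anticonservatism can appear at lower coverage.
* Event extraction enumerates isoform pairs; it is not a full splice-graph
  decomposition and assumes the annotation's isoforms expose the variation.
* The NB Wald expression test is approximate for very low counts; genes
  with means below a few reads are effectively untested.
* Consequence calls assume the annotated CDS and one skipped exon at a
  time; multi-exon skips and compensatory events are out of scope.
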