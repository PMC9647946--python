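# Methods

`magdecon` implements an isolate-guided strategy for deconvolving a
low-complexity metagenome into per-component metagenome-assembled genomes
(MAGs), together with the composition-, coverage- and marker-gene-based
validation machinery such a reconstruction needs, binning-evaluation
metrics, and a seeded consortium simulator that exercises every stage
without external data.

## The deconvolution model

The setting is a consortium of a handful of bacterial species, some of
which have been isolated in pure culture and genome-sequenced. Each
metagenome scaffold carries three signals:

1. **Alignment fraction (AF)** — the percentage of the scaffold covered by
   merged local alignments to an isolate genome. Alignment intervals are
   1-based inclusive; overlapping and abutting hits are merged before the
   covered length is summed, and hits shorter than 200 bp on the scaffold
   are dropped first. AF is computed on the scaffold (query) axis, because
   assignments are made per scaffold.
2. **Sequencing depth** — the mean per-base coverage after discarding
   100 bp at each scaffold end (coverage dips at contig termini). Species
   abundances differ by orders of magnitude, so each component occupies a
   closed depth interval [lo, hi]; a depth inside exactly one interval is
   assignable by coverage alone. Windowed depth (500-bp window, 250-bp
   step) supports a unimodality check: a clean MAG's window-depth histogram
   has one main peak.
3. **Tetranucleotide composition** — two statistics share one k-mer kernel.
   The *naive Bayes classifier (4-nt motif)* is an order-3 Markov model per
   component: log P(base | preceding trinucleotide), estimated from
   training sequence with a Laplace pseudocount (default 1), scored on the
   forward strand; the unnormalised log posterior of a sequence is the sum
   of log conditionals over its N-free 4-mer windows. The *TETRA
   signature* is the 256-vector of z-scores of observed tetranucleotide
   counts against a maximal-order Markov expectation formed from the
   sequence's own trinucleotide/dinucleotide counts (both strands counted);
   two sequences are compared by the Pearson correlation of their
   z-vectors.

The pipeline applies these signals in five steps: (2) AF >= 90% assigns a
scaffold to its isolate, multi-isolate conflicts resolved by maximum AF and
logged; (3) unaligned scaffolds inside exactly one coverage range prime the
uncultured MAGs, scaffolds inside several overlapping ranges are classified
by naive Bayes restricted to those components; (4) the remaining scaffolds
go by unique range where possible, otherwise by naive Bayes over all
components — accepted for an isolate only if that isolate also has an
alignment on the scaffold, else sent to the best-scoring uncultured
component; (5) a bin whose single-copy-gene table shows wholesale
duplication is two merged genomes and is split (below).

## Single-copy genes, completeness, AAI

Essential single-copy genes (SCGs) come from a declared universe of 107
markers. A gene with several SCG annotations keeps the minimum-e-value one
(ties: lexicographically smallest marker, logged). Completeness is
100 x (distinct SCGs present) / 107, reported at two decimals. A bin where
at least 25% of its present SCGs occur in more than one copy is flagged as
a suspected merge; the threshold is a design choice — a genuinely merged
pair duplicates essentially every shared marker, while occasional paralogs
stay far below it. SCG AAI between two genomes is the protein-length-
weighted mean of per-marker amino-acid identities; the comparison is valid
only if more than 95% of the smaller genome's markers are matched (the
smaller total is the conservative denominator, which the source definition
leaves open).

## Splitting a merged bin (step 5)

Seed scaffolds are those carrying SCGs present at more than one copy in
the bin. Each is scored against an *external* component's naive Bayes
model; because the two genomes sit at different compositional distances
from the external model, the scores are bimodal. By default scores are
normalised per scored window: the raw log posterior is proportional to
scaffold length, and with heterogeneous scaffold lengths the length signal
would swamp the genome signal. A fixed raw-scale cutoff (the classic
-1350 style) is supported with normalisation disabled, but it presumes
scaffolds of comparable length and must be re-derived per dataset.

The automatic cutoff is a deterministic two-means threshold: the split of
the sorted scores minimising within-cluster variance, accepted only when
it explains at least 0.70 of the total variance. (An optimal split of a
single Gaussian explains about 2/pi ~ 0.64, so 0.70 separates genuine
bimodality from noise; a largest-gap rule was tried first and is brittle
once clusters of tens of points have ~2-sigma separation.) The two seed
groups train one model each, and every scaffold of the bin is re-classified
between them.

## Validation by re-classification

Each MAG's scaffolds are sorted by decreasing depth, concatenated, and
shredded into 10-kb fragments stepping every 5 kb; a final sub-length
fragment is kept if it is at least 5 kb. Fragments are classified back
against whole-MAG models (TETRA correlation argmax, or naive Bayes), giving
a row-normalised true-vs-predicted accuracy matrix; total accuracy is the
fragment-count-weighted micro-average (whether to micro- or macro-average
was an open choice; micro matches "percentage of fragments correctly
classified"). Scaffolds under 10 kb are validated individually by naive
Bayes. Misclassification concentrates between compositionally related
genomes, so these accuracies are conservative.

## Evaluation metrics

With S_ij = base pairs of genome j in bin i:
Precision = sum_i max_j S_ij / sum S; Sensitivity = sum_j max_i S_ij /
(sum S + unbinned bp); F = 2PS/(P+S). A bin is correct when it is the
largest bin of its dominant genome. All ties are lexicographic and logged.
Units are base pairs throughout.

## The synthetic consortium

The generator states one world (defaults are not tuned):

| parameter | default | why |
|---|---|---|
| genomes | 6 x 300 kb | low-complexity consortium at desk scale |
| composition | order-3 Markov, rows ~ Dirichlet(1) | distinct learnable 4-mer signatures |
| coverage levels | 1000/300/100/40/21/20x | dominant-to-rare spread; the 21/20 pair overlaps by construction |
| isolates | the 300x and 100x genomes | dominant and rare components stay uncultured, as in real consortia |
| isolate completeness | 0.99 | near-complete isolate assemblies; dropped scaffolds exercise recovery |
| scaffold lengths | lognormal, median 8 kb, clipped 500 bp-50 kb | draft-assembly size spectrum |
| depth | Poisson per base x lognormal(sigma=0.05) scaffold jitter | shotgun coverage model |
| plasmid-like scaffolds | 2% of scaffolds at 10x their genome | abnormally-high-coverage contaminants of range inference |
| markers | 107 SCGs per genome, single copy | completeness/merge diagnostics |
| partial alignments | 10% of retained isolate scaffolds at AF 30-89% | exercises the low-AF recovery path |

Scaffolds are exact genome substrings — assembly error, chimeras and
read-level artefacts are *not* simulated, so a green end-to-end test
establishes that the decision logic is correct under the stated noise
model, not that the pipeline is robust to misassembly. Coverage ranges for
the pipeline are inferred from truth-labelled subsets with the known
plasmid-like scaffolds excluded explicitly (the automatic >10x-median rule
can miss a 10x outlier that jittered low); this mirrors the manual
curation a real analysis performs.

## Numerical choices and degenerate inputs

- TETRA motifs with zero or sub-unit variance (< 1 squared count) get
  z = 0, keeping homopolymers and other degenerate sequences finite.
- TETRA requires >= 1 kb of sequence (configurable); shorter input is an
  error advising concatenation.
- Naive Bayes windows containing N are skipped; a sequence with no
  scorable window is an error. Unobserved contexts fall back to the
  pseudocount-uniform distribution.
- The model prior is uniform, so posteriors reduce to likelihoods and a
  posterior cutoff behaves as a log-likelihood threshold.
- All classification/annotation ties break to the lexicographically
  smallest label and are logged.
- The chi-squared usage test reports p floored at 2.2e-16 (the customary
  printed bound) alongside the exact log-p; Yates correction is the 2x2
  default.
- Scaffolds below 500 bp are excluded from deconvolution, never
  force-assigned.

## Known limitations

- Number and coverage ranges of uncultured components come from
  configuration (or labelled subsets); the toolkit does not infer the
  component count from unlabelled depth histograms.
- Best-hit alignment chaining (delta-filter-style -q/-r) is assumed done
  upstream; the AF computation merges whatever intervals it is given.
- Step 5 splits one merged pair per bin; three-way merges would need
  iteration.
- The read-triage flag rule ("any rare 15-mer", canonical counting) is one
  reading of an ambiguous published criterion; the "all" rule is available
  as an option.
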