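# Methods

## Model and assumptions

`cisnet` scores a k-mer motif j for a target gene g by asking whether
promoters carrying j are over-represented among g's co-expression
neighborhood π_g, relative to the m background promoters. The implicit
model is that co-expressed genes are enriched for shared functional
binding sites, and that presence/absence of an exact k-mer in a
promoter is an adequate proxy for a binding site. Consequences of
those assumptions:

- The hypergeometric test uses only presence/absence (x, K are counts
  of motif-*containing* promoters); occurrence multiplicity is ignored.
  The Welch t-test variant uses mean occurrence counts instead and is
  therefore sensitive to multiplicity — the unit suite tests this
  contrast explicitly.
- Neighborhoods always include the gene itself (adjacency diagonal is
  1). Excluding self is available (`include_self=False`) for
  sensitivity analysis.
- Genes with empty neighborhoods (q = 1, self only) are still scored
  but rarely significant; they are noted in the log.

The score transform is s = min(cap, −log10 p) with cap 40. The sign
merits a note: the transform must be *decreasing* in p for the score
range 0..cap and the correspondence cutoff 2 ↔ p = 0.01 to hold, so
the negated logarithm is used. p is floored at 1e−300 before the
logarithm; the floor is invisible after capping. Edges of the bipartite
cis-regulatory network require s strictly greater than the cutoff, so
p = 1 pairs (s = 0) are never edges even at cutoff 0.

No multiple-testing correction is applied by default — the method is
calibrated on raw p-values with score cutoffs — but Benjamini–Hochberg
q-values can be emitted alongside (`--qvalues`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 6 | motif length; l = 4^k candidate motifs (4096) |
| cap | 40 | ceiling on −log10 p, guards numerical precision |
| cutoff | 2 | strict score threshold for CRN edges (p = 0.01); 17–30 give sparse networks for visual analysis |
| rank_threshold | required | mutual-rank cutoff for the co-expression network; ~120 (yeast stress data) and ~100 (Arabidopsis) are the published operating points. Automatic topology-based selection is out of scope: the threshold is always explicit |
| top_n | optional | keep only the N highest-variance genes before network building (3000 in the published yeast analysis) |
| n_features | 400 | motif columns entering each per-array regression |

Counting conventions (all deterministic): overlapping windows each
count (AAAAAAA contains AAAAAA twice); forward strand only by default,
preserving the full 4^k column space (`--collapse-revcomp` pools each
word with its reverse complement); windows containing N or any IUPAC
ambiguity code contribute nothing; input is uppercased and soft-masking
is not treated specially.

## Numerical choices and tie-breaking

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the
  enrichment matrix deduplicates identical (x, K, q) triples before
  calling it. The acceptance suite checks the tail against exhaustive
  subset enumeration (all C(m,q) draws, m ≤ 12) to 1e−12.
- The t-test matrix is computed in closed form from neighborhood group
  sums (Welch statistic and Satterthwaite df), one-sided in the
  over-representation direction by default; cells with a group smaller
  than 2, or zero variance in both groups and equal means, get p = 1;
  zero variance with unequal means degenerates to the floor/1 by
  direction. A unit test cross-checks random cases against
  `scipy.stats.ttest_ind`.
- Correlation-rank ties in network building, variance ties in top-N
  selection, and feature-selection ties all break by lexicographic
  gene/motif id, so runs are byte-reproducible.
- Quantile normalization maps every column onto the across-column mean
  of order statistics; tied values within a column receive the mean of
  the quantile slots they span.
- Zero-variance expression rows are dropped (with a warning) before
  correlation ranking; zero-variance score rows yield undefined
  similarities that can never become co-regulatory edges, while the
  remaining pairs of such genes still count as non-edges in the
  confusion-matrix universe.
- Regression uses `numpy.linalg.lstsq`: rank-deficient designs get the
  minimum-norm solution. Feature selection ranks motifs by |PCC| with
  the expression vector (signed mode optional) so repressive motifs are
  selectable; RMSE/PCC are in-sample, matching the evaluation protocol
  this package follows (a train/test split is deliberately not the
  default).
- PPV and TPR are defined as 0 when their denominators are 0.

## Synthetic benchmark: what it emulates, and what it does not

The generator emulates the full input suite: a background "genome" of m
i.i.d. multinomial promoters (default uniform base composition, m =
1000, L = 500 bp), gene modules with one exact 6-mer planted per module
gene with probability 0.9 (overwriting a disjoint window, so lengths
are preserved) against a 5% background insertion rate, a
module-structured expression matrix (one standard-normal latent profile
per module, expression = effect × latent + N(0, sd) noise; defaults
effect 1, sd 0.3, 60 arrays → expected within-module correlation
1/(1 + 0.09) ≈ 0.92), a ground-truth gene–motif edge list, and a
module-clique reference network. Defaults were chosen as a realistic
desk-scale regime: module sizes (30) and promoter lengths match small
yeast regulons, and the 5% background rate plus ~11% chance occurrence
of any 6-mer in 500 uniform bp give a non-trivial null.

The generator does *not* emulate realistic nucleotide composition
(no GC skew, no repeats), degenerate or variably spaced motifs,
condition-specific regulation, or heavy-tailed expression noise.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions, not that it attains any
particular accuracy on real genomes, where motif degeneracy and
correlated backgrounds make the problem harder.

Benchmark problem sizes in the test suite (m = 1000 promoters, n = 300
targets, three 30-gene modules, five seeds) were chosen so the whole
recovery study runs in well under a minute while leaving the planted
signal non-trivial.

## Known limitations

- Exact k-mers cannot represent degenerate sites; closely related words
  appear as separate, correlated columns (visible in the worked example
  as significant flanking words around a planted motif).
- The hypergeometric test treats promoters as exchangeable; shared
  composition biases (e.g. CpG-rich promoters) inflate apparent
  enrichment on real data.
- Mutual-rank threshold selection is the user's responsibility; the
  edge set grows monotonically with the threshold, so a sweep is cheap.
- In-sample regression PCC is optimistic in absolute terms (feature
  selection from 4^k columns overfits); it is meaningful as a *relative*
  comparison between feature matrices, which is how the evaluation uses
  it — the row-permuted null in the acceptance suite quantifies the
  selection-bias floor.
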