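# Methods

## The problem and the model

`histact` predicts whether a gene is transcribed ("active") or not
("inactive") from the presence or absence of histone modifications in 24
nucleosome-sized (200-bp) regions anchored at its transcription start and
termination sites: TSS-10 … TSS-1, TSS, TSS+1, TSS+2, TTS, TTS+1 … TTS+10.
Transcription activity is treated as strictly binary.  The analysis has
four stages:

1. **Binarization and feature construction.**  Per-bin ChIP tag counts are
   collapsed to presence/absence — a bin carries a mark iff its count
   exceeds a threshold (default 0, i.e. any signal counts).  This guards
   against the occasional bins with counts in the hundreds dominating any
   count-weighted statistic.  The bins × marks matrix is then gathered into
   a genes × (region, mark) binary feature matrix via each gene's 24 region
   bins.  Upstream/downstream are strand-aware: for a minus-strand gene,
   "upstream of the TSS" means higher genomic coordinates.  Coordinates are
   0-based half-open and the bin holding position p is `p // 200`; both
   conventions are fixed choices, since raw HHMD-style tables do not state
   one.
2. **Frequency profiling.**  Genes are ranked by mean log2 expression and
   cut into G = 19 contiguous groups (sizes differing by at most one; the
   ceil-sized groups take the top ranks).  For a feature, the occurrence
   frequency of group g is F_g = N_g / N_all.  Under no association each
   F_g ≈ 1/G ≈ 0.053.  The *transition point* — where informative marks'
   profiles cross the uniform line — is operationalized as the group
   minimizing the mean absolute deviation of the profiles from 1/G (ties to
   the smaller group).  The crossing is only described qualitatively in the
   literature this follows; the argmin definition is the simplest testable
   reading.
3. **Tree induction and thresholding.**  A binary decision tree is grown on
   the feature matrix of the expression extremes (top and bottom sixth of
   genes by default), labelled active/inactive.  Every gene is then routed
   through the tree and designated x_i = +1 (active-majority leaf) or -1.
   With genes ordered by decreasing expression, the cumulative sum
   Y(g) = Σ_{i≤g} x_i peaks where +1 designations stop dominating;
   g_max = argmax Y(g) (smallest g on ties) sets the activity threshold:
   genes at ranks ≤ g_max are active, and the expression value at g_max is
   the log2 threshold.  An independent procedure tests, for each candidate
   rank, the +1 proportion above and below the cut against the overall
   proportion (exact two-sided binomial tests) and picks the rank
   minimizing the sum of the two p-values; the two procedures agree to a
   few ranks on planted data.
4. **Evaluation and MDR confirmation.**  *Prediction accuracy frequency* is
   the fraction of genes whose ±1 designation matches the threshold label.
   Evaluation designs: per-region trees (24 analyses on one region's marks
   each), a random half/half train–test split on all features, and
   single-mark trees (24 region columns of one mark), rankable across all
   39 marks.  The multifactor-dimensionality-reduction search exhaustively
   scores attribute combinations: training genes are binned into the 2^c
   cells of a c-mark combination, a cell is high-risk iff its
   active:inactive ratio strictly exceeds the overall training ratio
   (empty or tied cells low-risk), and held-out genes are scored by
   balanced accuracy over a seeded stratified 10-fold cross-validation
   ("Tba").  Unlike greedy tree growth, MDR considers combinations that
   share no prefix, so agreement between the two methods is a meaningful
   cross-check.

## Tree growth details

Growth is best-first on Gini impurity: the frontier leaf offering the
largest total (count-weighted) impurity decrease is split until k internal
nodes exist or no split helps.  Consequences used throughout: the k-node
tree is nested in the (k+1)-node tree, so "pruned to k nodes" is well
defined, and training accuracy is non-decreasing in k.  This is a
deliberate simplification of classic CART's depth-first growth plus
cost-complexity prune path; equivalence with any particular CART
implementation is not claimed.

Determinism receives special care.  Within a leaf, maximizing the Gini
gain over features is equivalent to minimizing
h = n1a·n1i/n1 + n0a·n0i/n0 over the candidate split counts; this
comparison is done in exact int64 arithmetic (cross-multiplication), so
mathematically tied features resolve exactly to the first in canonical
order — regions in layout order, marks alphabetical within a region.
Floating-point gains would otherwise break ties platform-dependently.
Frontier ties resolve to the larger leaf, then to the earlier-created
leaf.  Leaf-label ties go to "inactive", keeping active calls strictly
evidence-driven.  Degenerate input (one class) yields a single-leaf tree
with a warning rather than an error.

Significance of a k-node tree is assessed by permutation: B (default 200,
minimum 19) label shuffles, p = (1 + #{permuted training accuracy ≥
observed}) / (B + 1).  This replaces the unspecified internal P value of
the original CART software with something exactly calibrated by
construction.

## Exact binomial tests in deep tails

The alternative threshold procedure needs exact two-sided binomial
p-values at every candidate rank.  Near a strong change-point these are
astronomically small: naive tail probabilities underflow to 0 and the
argmin degenerates to the left edge of a plateau (observed as a ~3%-of-n
bias before the fix).  `exact_binom_two_sided` therefore computes
minimum-likelihood two-sided p-values in log space, with tail sums
evaluated as windowed log-sum-exp over `binom.logpmf` terms (window: 16 SD
plus a 256-term margin; truncated mass is far below double-precision
relative accuracy).  The implementation matches `scipy.stats.binomtest` to
~1e-13 relative error where the latter does not underflow, and remains
finite and strictly ordered arbitrarily deep.  Rank minimization happens
on log(p_above + p_below) via `logaddexp`; ties within 1e-9 (log scale)
break to the smaller rank.

## The synthetic generator

The generator emulates the statistical skeleton the analysis assumes of
CD4+ T-cell inputs, with a known ground truth:

- latent state z ~ Bernoulli(pi_active) per gene (default 0.5);
- per-sample log2 expression ~ Normal(mu_z, sigma) with mu_active = 8,
  mu_inactive = 4, sigma = 1 — a cleanly separated RMA-scale mixture whose
  midpoint (6.0) plays the role of the true activity threshold;
- presence of mark m at region r ~ Bernoulli(p(m, r | z)).  The `cd4_like`
  preset uses the 39 CD4 modification names with H2BK5ac planted at
  TSS-3 … TSS (0.8 active / 0.2 inactive), H3K36me3 at TTS … TTS+3
  (0.6 / 0.3), and all other pairs at the weakly informative background
  0.35 / 0.30;
- genes sit on one synthetic chromosome in non-overlapping 40-bin strides,
  alternating strands, with 10-bin flanks so no region falls off the
  chromosome; overlapping placements raise an error;
- counts are emitted as 1 when present (optionally 1 + Poisson, to
  exercise binarization of real-valued counts).

Default n_samples is 8 rather than the 78 arrays of the real compendium;
the averaging logic is sample-count-agnostic and 8 keeps tests fast while
still exercising it.  What the generator deliberately omits: spatial
autocorrelation along the chromosome, nucleosome positioning, correlated
marks, antibody-control background, and heavy-tailed expression.  Passing
tests therefore demonstrate that the pipeline recovers planted structure
of the assumed form — not that real chromatin obeys that form.

## Numerical and design choices

- Expression values are taken as already log2 (RMA convention); the
  pipeline never re-logs, and thresholds are reported on that scale.
- Gene ranking ties break by gene id (stable), making partitions and
  thresholds permutation-invariant to input row order.
- Regions before the chromosome start are encoded 0-with-mask rather than
  dropping the gene, keeping gene universes aligned across stages; genes
  on chromosomes absent from the signal data get fully masked zero rows
  with a warning.
- The argmax-Y tie rule (smallest g) makes the active set minimal; the
  threshold gene itself is active.
- Train/test splits are uniform over genes with a recorded seed; MDR folds
  are stratified by class with a recorded seed; `mdr_search` ties keep the
  lexicographically first combination; a work estimate guards the
  combinatorial budget (full 39-choose-5 is supported but must be
  requested with a raised cap).
- Problem sizes in the test suite: planted-recovery properties use 20
  replicate datasets of 5000 genes; permutation-calibration uses 30
  replicates at n = 120 with B = 99; the acceptance script runs the full
  pipeline at n = 3000.  These sizes give Monte-Carlo error comfortably
  inside the asserted bounds.

## Known limitations

- The tree is not classic CART: no surrogate splits, no cost-complexity
  pruning, no missing-value handling beyond the region mask, binary
  classification only.
- The transition-point and P-minimization operationalizations are the
  package's own precise readings of procedures described only loosely in
  the source literature; alternatives (e.g. slope-based crossing
  detection) could shift results by a group or a few ranks.
- Headline real-data numbers (e.g. ~75% test accuracy, Y_max = 4977,
  threshold 5.92) require the external CD4+ T-cell histone maps and the
  78-array expression compendium; they are documented for scale but not
  reproduced by the synthetic conditions, under which accuracies are
  higher (~90%) because the planted signal is sharper than real chromatin.
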