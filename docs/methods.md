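# Methods

## Problem and model

Bacterial small RNAs (sRNAs) are 50–500 nt regulators that are poorly
conserved at the sequence level but sit in characteristic genomic
contexts: transcribed from their own promoter, terminated by a
Rho-independent (intrinsic) terminator, and usually intergenic. The
package turns each candidate locus into a seven-dimensional feature
vector (structure stability; signed promoter distance; terminator
distance; signed gaps and strand agreement with the two flanking ORFs)
and treats prioritization as binary probabilistic classification of
bona fide sRNAs against random genomic loci. The classifier's
probability output is the ranking score; with the heavily unbalanced
evaluation sets this implies, AUPRC — not ROC AUC — is the headline
metric, and precision at a recall cutoff directly estimates the success
rate of a wet-lab validation campaign over the top of the ranking.

## Coordinate and feature conventions

All coordinates are BED-style 0-based half-open. Genomes default to
circular (bacterial chromosomes), so upstream windows and flanking-ORF
searches wrap around the origin; a flag disables wrapping for draft
contigs. Design choices where the feature definitions were genuinely
open:

* **Promoter distance sign.** The upstream window runs from 150 nt
  before the 5′ start to the 3′ end. We define d > 0 for boxes upstream
  of the 5′ start (bounded by 150) and d ≤ 0 for boxes inside the
  candidate, measured to the box's 5′-most base; the closest |d| wins
  and ties prefer the upstream site. The −1000 sentinel is therefore
  strictly outside the attainable range, which keeps it separable for
  the classifiers.
* **Terminator search.** Restricted to same-strand terminators
  overlapping the candidate or downstream of its 3′ end, because
  intrinsic termination acts in cis at the 3′ end; antisense terminators
  are excluded. Distances are clamped at the 1000 sentinel.
* **Left/right ORFs** are genome-axis notions (lower/higher
  coordinates) independent of the candidate's strand; any overlap clamps
  the distance to 0. Ties between equally near ORFs break toward the
  greater end (left) / smaller start (right), then by name, for
  determinism.

## Built-in predictors

External promoter/terminator/structure predictors are exchangeable
providers: parsed report files (BPROM plain text, TransTermHP
predictions), BED files, precomputed energy tables, or the built-ins
below. The built-ins are deliberately simple, documented algorithms —
not re-implementations of the external tools' scoring:

* **Fold** (`fold_mfe`): weighted Nussinov minimization over
  pseudoknot-free structures with hairpin loops ≥ 3 nt; pair weights
  GC −3, AU −2, GU −1 (dimensionless; lower = more stable). Ties break
  toward fewer pairs, then the lexicographically smallest dot-bracket.
  The DP is exact and O(n³); the traceback is optional because the
  pipeline consumes only the energy and exact lexicographic tie-breaking
  can be expensive on degenerate long sequences.
* **−10 box scan** (`scan_minus10`): a 4×6 log₂-odds PWM built from a
  soft TATAAT consensus (0.7 consensus / 0.1 other, uniform background),
  packaged as a TSV with its reporting threshold (6.0, which admits the
  consensus and any single mismatch but no double mismatch).
* **Terminator detector** (`detect_terminators`): both strands are
  scanned for a stem of ≥ 6 Watson–Crick/GU pairs (≤ 1 mismatch), a
  3–8 nt loop, and ≥ 4 T in the first 8 nt within 2 nt of the stem;
  overlapping same-strand calls merge keeping the higher score
  (stem pairs + tail T count). All thresholds are arguments.

## Dataset construction

Negatives are drawn uniformly at random, matched in length and strand
to each positive, and rejected only if they share a base with any
positive (they may overlap each other and ORFs — random loci falling
into coding sequence is precisely the signal). Shuffled-sequence
negatives are deliberately unsupported: shuffling preserves genomic
context, which is what these features measure. The default pool is 10
negatives per positive; training draws 3 per training positive (the
first 3 of each positive's pool, so lower-ratio training sets are
proper subsets of higher-ratio ones) and all remaining negatives are
held out for testing. Positives split 80/20 with round-half-up rounding
of the training count. All draws are `numpy` `default_rng`-seeded and
byte-reproducible.

## Classifiers

scikit-learn estimators behind a uniform config surface, with defaults
fixed at the LOO-CV-AUC-tuned settings for this task: LR with balanced
class weights; a one-hidden-layer 400-unit logistic MLP trained by plain
SGD at constant rate 0.9 with L2 1e-4; RF with 400 trees, depth 20, Gini
splits, 2 features per split; AdaBoost over 100 depth-1 stumps; and
stochastic gradient boosting with 50 depth-15 trees, minimum leaf 5,
subsample 0.9. `tune_loocv` re-derives a best config from a grid by
pooled leave-one-out AUC (ties to grid order). Features enter unscaled.

## Evaluation machinery

* PR curves use the step-wise (right-continuous) convention: thresholds
  sweep distinct scores descending, tied scores enter together, and
  AUPRC = Σ precisionᵢ·Δrecallᵢ. This is conservative and avoids the
  optimism of linear PR interpolation.
* Winner-gets-all reporting ranks give tied models the shared minimum
  rank; the Friedman statistic is computed on average ranks (it is
  ill-defined on competition ranks), χ²_F = 12N/(k(k+1))·(ΣR̄ⱼ² −
  k(k+1)²/4) on k−1 df.
* Post-hocs: Nemenyi via the studentized range (critical difference
  q_α·√(k(k+1)/6N)); Quade's range-weighted rank comparisons and
  Conover's t-type comparisons on (N−1)(k−1) df, both with
  Benjamini–Hochberg adjustment of the pairwise p-values (Nemenyi p's
  are already familywise). `posthoc` takes the raw models × test-sets
  value matrix because Quade needs the within-block ranges, not just
  ranks.
* Attribute importance is the out-of-bag mean decrease in accuracy of a
  random forest: per tree, accuracy on its out-of-bag samples minus
  accuracy after permuting one feature column there, averaged over trees
  and repeats. Only RF models carry the OOB bookkeeping
  (`estimators_samples_`); other families are rejected.

## Synthetic fixture

`simulate_genome` builds a seeded toy chromosome emulating the
statistics the pipeline assumes: 40 non-overlapping ORFs of 400–1200 nt
on a 50 kb circular genome (~64% coding, bacterial-like), with 20
planted positives of 50–300 nt in distinct intergenic gaps, strands
alternating. Each positive gets an exact TATAAT box 35 nt upstream of
its 5′ start and a canonical 8-bp-stem hairpin + 8T terminator 20 nt
downstream of its 3′ end — both inside the features' search ranges so
the sentinels never fire for positives. Because random background also
contains TATAAT-like boxes and hairpin/U-tract loci, a deterministic
scrub pass re-randomizes any background motif that would displace a
planted element as the closest call (never touching planted
coordinates) until the built-in predictors recover the planted
distances exactly for every positive; re-randomization is memoryless,
so this converges in a handful of passes.

What the fixture does *not* emulate: codon usage, operons, transcription
units, GC skew, real promoter/terminator sequence diversity, or
heterogeneous sRNA structure. Passing the recovery tests therefore shows
the pipeline's plumbing and the classifiers' ability to exploit planted
context signal; it does not certify performance on real genomes, where
promoter/terminator predictors miss many true sites and a substantial
minority of genuine sRNAs overlap ORFs.

## Problem sizes and numerical notes

The shipped test suite and the acceptance script run the fixture at its
default size (20 positives, 10× negative pool, ~220 fold computations),
verify the distance features on 1,000 random annotation fixtures against
brute-force scans, the fold on hundreds of random sequences of length
≤ 14 against exhaustive enumeration, and the curve statistics on 1,000
random instances against confusion-matrix brute force — sizes chosen so
the whole suite completes in a few minutes on one core. Float equality
in the fold traceback relies on identical operation ordering between the
DP and the traceback; default pair weights are integers, so sums are
exact. Degenerate inputs (single-class labels, empty ORF sets,
non-finite features, infeasible simulation geometry) raise informative
errors rather than propagating silently.

## Known limitations

* The built-in fold reports a dimensionless Nussinov score, not a
  thermodynamic free energy; any monotone stability score works for the
  classifiers, and precomputed energies can be supplied per candidate.
* Promoter boxes straddling a circular genome's origin have no
  single-interval representation and are dropped by the PWM provider.
* `parse_bprom` maps window-relative positions for one window at a
  time; characterizing many candidates from per-candidate BPROM reports
  requires one parse per window (the CLI exposes the whole-genome case).
* LOO-CV tuning refits one model per instance and is intended for the
  small training sets typical of this problem (tens to hundreds of
  rows).
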