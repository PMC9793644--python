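# Methods

## Problem and data model

The package classifies long circular RNAs (positives) against other long
non-coding RNAs (negatives) from (i) the transcript sequence and (ii)
optional genomic context: the span of the circularized interval, whose
endpoints are the back-splice-junction coordinates, plus a BED annotation
of Alu elements. Sequences are normalized to uppercase DNA (U→T); N is
tolerated up to 5% per transcript for the physicochemical encoders.
Dataset preparation offers a 200-nt minimum-length filter and a greedy
redundancy filter: records are visited longest-first and dropped when
their word identity (shared 5-mer multiset over the 5-mers of the shorter
sequence) to a retained record reaches 0.8. This is a deterministic,
testable stand-in for alignment-based clustering tools; it is stricter in
spirit than true alignment identity for shuffled sequences and is meant
for dataset de-duplication, not homology search.

## Feature extraction (170 columns)

* **Trinucleotide frequencies (64).** Overlapping 3-mer counts divided by
  the sequence length N (so components sum to (N−2)/N, not 1 — the
  denominator is the transcript length by definition, and we keep that
  convention). Windows containing N are skipped.
* **ORF statistics (4).** Per forward frame, the longest complete ORF
  (ATG through the first in-frame stop, stop included, length a multiple
  of 3; an ATG with no downstream in-frame stop scores 0). Features:
  longest ORF length, its coverage of the transcript, the mean of the
  three frame lengths over the transcript length, and the spread
  d = ((x0−x1)² + (x0−x2)² + (x1−x2)²)/2 computed on per-frame
  *coverages* so that d is scale-free and comparable across transcript
  lengths (raw lengths would make d grow quadratically with transcript
  size). Reverse-strand ORFs are out of scope.
* **DACC (72).** Auto and cross covariance of six standardized B-DNA
  dinucleotide helical parameters (Twist, Tilt, Roll, Shift, Slide,
  Rise) at lags 1..LAG. The property mean is taken over the sequence's
  own dinucleotides; each (property, lag) term divides by L−lag−1.
  Components are ordered DAC (property-major, lags ascending) then DCC
  over ordered property pairs. Positions whose dinucleotide contains N
  are excluded from sums and denominators.
* **SCPseDNC (28).** The 16 dinucleotide frequencies (normalized to sum
  to 1) extended by λ·Λ correlation factors, tier-major: for each
  distance m = 1..λ, one factor per property, each the average product of
  the property values at positions i and i+m over i = 1..L−m−2. All
  components share the denominator 1 + w·Σθ, so the vector sums to 1
  exactly. With a standardized property table individual θ can be
  negative; sum-to-one is the invariant we guarantee, not
  nonnegativity.
* **Alu (1).** For each window size W ∈ {1000, 2000}, the number of Alu
  intervals overlapping [start−W, start) ∪ [end, end+W) (half-open,
  clipped at 0, counted once per window size). The default single feature
  is the sum over both window sizes; per-window columns are available via
  `EncoderConfig(alu_per_window=True)` (171 columns). Transcripts without
  a locus — linear lncRNAs have no back-splice site — score 0, with a
  logged warning for absent chromosomes.
* **Tandem repeats (1).** A deterministic exact-match detector: maximal
  runs where a motif of period 1–6 repeats ≥ 3 times; runs are scanned
  smallest-period first and a run overlapping positions already claimed
  by a smaller period is suppressed (so a homopolymer is one period-1
  call). The feature is total repeat copies per kilobase. This replaces
  alignment-scored repeat finders with a hand-verifiable definition; it
  calls only perfect repeats.

### Parameter defaults and the 170 total

LAG (maximum covariance lag), λ (maximum correlation tier) and w (the
SCPseDNC weight) default to 2, 2 and 0.1. With six properties this makes
the groups 64 + 4 + 72 + 28 + 1 + 1 = 170, the documented default feature
space. The six properties have no canonical printed values; the shipped
table is the widely circulated standardized B-DNA dinucleotide parameter
set, re-standardized to exact zero mean / unit variance per property on
load, and any complete 16 × 6 table can be supplied as TSV
(`PropertyTable.from_tsv`), so results can be reproduced under alternative
property values.

## Feature selection

Mutual information uses the plug-in estimate in bits over discretized
values; continuous features are quantile-binned into ≤ 10 levels with
edges fitted on the training split only (constant columns collapse to one
level; already-discrete columns keep their levels). Ranking is the
canonical greedy mRMR: the first feature maximizes I(x; c); each next
pick maximizes relevance minus the mean MI with the selected set (MID,
default) or the quotient (MIQ); ties break toward the lower column index.
The default retained dimension is 110 of 170. `sweep_dimensions` computes
one ranking on the training split and re-trains/evaluates at each
dimension in {30, 50, …, 170}, avoiding test leakage by construction.

## Stacking classifier

Base learners are a random forest, XGBoost and LightGBM at library
defaults with the propagated seed and single-threaded fits — defaults are
the only reproducible choice absent a tuning protocol, and every setting
is swappable through `StackingConfig` (any object with `fit` /
`predict_proba` works, which is how the test suite audits the fold logic
with instrumented stubs). Folds are stratified (5 by default) so class
balance survives the split; meta-features are out-of-fold positive-class
probabilities, strictly more informative than hard labels; the
meta-learner is logistic regression. At inference each base learner's
five fold-models are probability-averaged before the meta-learner; the
binary call threshold is 0.5 (configurable). MCC is reported as 0 with a
warning when its denominator vanishes. Models persist as a directory:
JSON metadata plus joblib-serialized estimators.

## Synthetic benchmark

The generator emulates the signal classes the features detect, on a
synthetic chromosome where each transcript owns a disjoint slab (so Alu
counts never bleed between transcripts):

* background: second-order Markov chain at GC 0.42, giving non-trivial
  dinucleotide/trinucleotide structure;
* class signal: CpG-containing trinucleotides enriched 3× in positives;
  complete ORFs (30–60% of transcript length) planted with probability
  0.9 vs 0.1; tandem runs planted at 1.0 vs 0.1 per kb; Alu elements
  (300 bp) dropped into the 2000-nt flanks at Poisson rates 3.0 vs 0.3;
* `null_config()` sets the bias to 1 and equalizes all rates.

Lengths are uniform on [200, 3000]. Everything derives from one seed and
a JSON manifest records every planted element. Two caveats on realism:
the planted tandem signal is small relative to the background run density
the exact-match detector sees (~160 copies/kb), so that feature carries
little class signal under defaults; and real circRNA/lncRNA data differ
in ways the generator does not model (splicing structure, expression
biases, genome-wide repeat landscapes). Passing the end-to-end tests
therefore demonstrates that the pipeline recovers planted signal of these
kinds — not benchmark performance on real human or mouse data.

## Numerical and testing choices

Encoders are vectorized but verified, to 1e−9, against literal-loop
brute-force oracles kept independent in the test suite; mRMR is verified
against a from-scratch greedy recomputation; the stacking fold logic is
audited with stub learners that record their training rows. End-to-end
acceptance uses 1000 + 1000 transcripts over 5 seeds for the separable
condition and 500 + 500 for the null condition — sizes chosen to make the
stochastic assertions (held-out ACC ≥ 0.95; |MCC| ≤ 0.15 under null)
stable while keeping the default test run fast.

## Known limitations

* The redundancy filter is word-based, not alignment-based; identity
  values are not comparable to alignment identity for distant pairs.
* ORF detection considers the given strand only and requires a stop
  codon (an `allow_open_ended` relaxation is a natural extension).
* The mutual-information estimator is the binned plug-in; with ≤ 10
  quantile bins it is biased upward for small samples, which affects
  absolute relevance values but not materially the greedy ordering.
* Alu counting treats both flanks strand-agnostically and does not model
  reverse-complement Alu pairing.
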