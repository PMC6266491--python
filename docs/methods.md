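# Methods

## Model

`circpot` frames circRNA-potential prediction as binary classification of
transcript sequences. Three classifier roles are supported under one
training recipe: circRNA vs protein-coding gene (`cp-pcg`), circRNA vs
lncRNA (`cp-lncrna`), and stem-cell-expressed circRNA vs not
(`sp-circrna`); reference tree counts of 80/100/60 are carried for the
three names, but any tree count can be fixed or tuned per dataset.

The classifier is a cross-validation ensemble of random forests: a
stratified five-fold split, one forest of unpruned bootstrap-sampled trees
per fold (each tree trains on about two thirds of its fold-training rows;
the rest are out-of-bag). Stratification is a deliberate choice — it
guards against degenerate folds on small or imbalanced data.

### Fractile scores and rank aggregation

Raw forest probabilities are not comparable across folds, so each fold
keeps its held-out validation score distribution. A new score *s* is
mapped to its fractile

    F(s) = (#{v < s} + 0.5 · #{v = s}) / n

within that distribution, and the five fractiles are averaged. Half-weight
ties make the fractiles of a distribution against itself exactly uniform,
which the tests exploit (Kolmogorov distance to uniform below 0.05 at
n = 1000). The mean fractile is displayed as a percentage, rounded to an
integer.

### FPR calibration

A held-out negative set maps mean-fractile cutoffs to empirical false
positive rates: FPR(t) = #{f ≥ t}/n on a 101-point cutoff grid over
[0, 1]. Lookup is a step function (largest tabulated cutoff ≤ query);
this reproduces the empirical tail fraction exactly at tabulated cutoffs
and is conservative between them. In the packaged training flow, 20% of
the supplied negatives are held out for calibration by default; an
independent negative set can be passed instead, which is the better choice
when one is available since calibration on training-distribution negatives
inherits their composition.

### Feature encoding

Up to 178 features in four groups; three profiles are exposed: `gc_len`
(GC content + length, a deliberately weak baseline), `sequence_only`
(basic + graph; the path available for plain FASTA input) and `all`
(adds conservation and annotation features, which need tracks and genomic
context).

* Basic (70): length; AG, GT, GTAG, AGGT frequencies; GC content; 64
  trinucleotide frequencies. Frequency denominators are
  overlapping-window counts for the motif's own length, making the
  features scale-free in sequence length. Windows containing N are
  excluded from both numerator and denominator of trinucleotide
  frequencies; a sequence whose every window contains N yields zeros
  rather than an error. Length enters raw and is min-max normalized like
  everything else.
* Graph (Top-K, default 101): neighborhood-pair features on the
  nucleotide path graph. For roots i ≤ j with j − i ≤ D and radius
  r ≤ R, the canonical key is `(r, d, unordered pair of canonical rooted
  neighborhoods)`; a rooted path neighborhood is canonicalized over
  reflection by ordering its two arms lexicographically, so a sequence
  and its reverse encode identically (a documented property of this
  symmetric encoding). Keys hash into `hash_dim` bins (default 32768)
  via CRC-32 with a seed-mixed initial value — fast, deterministic and
  seedable; collisions are accepted as in standard hashed kernels.
  Defaults R = 2, D = 4 are declared, not derived: the choice trades
  context size against dimensionality, and K ∈ {50, 101, 200} behaves
  similarly in cross-validation on signaled synthetic data. Selection
  fits a 100-tree random forest on the hashed counts and keeps the Top-K
  by impurity importance, ties broken toward the lower id. The packaged
  workflow ranks on the training sequences themselves; with abundant data
  a separate ranking subset is preferable (feature selection then cannot
  interact with model tuning), and `GraphFeatureSelector` accepts any
  sequence set for that purpose.
  One boundary effect is worth noting: neighborhoods truncate at sequence
  ends, so a subsequence's keys recur in a supersequence only for root
  pairs at least R bases from the subsequence's ends; the property test
  checks exactly that interior form.
* Conservation (2): mean and population SD of the per-base track values.
  Population (ddof = 0) SD is fixed arbitrarily but deliberately — either
  convention is defensible, one must be pinned. Uncovered bases are NaN
  and skipped, never zero-filled: zero is a meaningful conservation value.
* Other (5): ALU overlap fraction (fraction of bases covered by repeat
  features whose name starts with "ALU", case-insensitively; chosen over
  count-per-kb as the bounded, length-free reading), tandem-repeat
  coverage, longest-ORF length, ORF propensity (ORF length / sequence
  length) and SNP density (unique variant positions per base).

The ORF is defined on the three forward frames only, requires an in-frame
stop, and counts start and stop codons — a deterministic, oracle-checkable
definition rather than a heuristic coding-potential score. Tandem repeats
are exact maximal arrays with period ≤ 12, ≥ 2 full copies and span ≥ 6 nt
(configurable); this replaces alignment-scored repeat finders with a
definition that an exhaustive enumeration oracle can verify.

Records read from FASTA carry no genomic position, so the `all` profile
needs either BED + genome input or tracks keyed by transcript id (the
query interval then spans the whole sequence on a contig named after the
record). Normalization is min-max to [0, 1] fitted on training rows and
clipped at apply time; constant features map to 0.

## Synthetic data

The generator emulates a labeled circRNA-style training set: two classes
of i.i.d. GC-biased sequences with Poisson-planted motifs, placed with
random strand on a toy genome (minus-strand records store the reverse
complement, so BED extraction round-trips), plus matching tracks. Defaults
are the package's study conditions: 500 + 500 sequences of 200–1000 nt
(mirroring the ≥ 200 nt dataset filter), GTAG at 2.0 vs 0.5 per 100 nt,
GC 0.55 vs 0.45, conservation mean shift +0.5 for positives at 5 nt block
resolution, ALU-like 300 nt intervals at carrier probability 0.4 for
positives and half that for negatives (the single `alu_prob` knob sets the
positive-class rate), class-neutral L1 noise repeats, and 0.01 variants
per base in both classes. The null generator gives both labels the
negative-class distribution.

What this does and does not show: the signal channels touch every feature
group, so passing tests demonstrate that each feature path carries signal
through selection, training, fractile aggregation and calibration, and
that a signal-free dataset stays at chance. The sequences are i.i.d. per
base — no splice structure, no real backsplice junctions, no homology
between records, no genome-scale composition heterogeneity — so test AUCs
near 1.0 say nothing about performance on real transcripts, where
reported AUCs for this class of method are in the 0.7–0.9 range.

## Numerical and design choices

* All randomness flows from explicit seeds; fold forests get seeds
  derived arithmetically from the ensemble seed, so training, selection
  and prediction are reproducible bit-for-bit (byte-identical prediction
  TSVs across runs).
* The dataset filter keeps length exactly equal to the minimum ("shorter
  than" is removed); exclusion overlap is strand-agnostic single-base
  overlap — the most permissive reading, which avoids leakage between
  classes sharing a locus.
* BED is 0-based half-open throughout; missing strand defaults to "+";
  minus-strand intervals yield the reverse complement.
* Tree-count tuning maximizes the mean per-fold CV AUC over 10…100
  step 10; ties take the smallest count.
* AUC is the Mann–Whitney form (ties 0.5), computed via
  `roc_auc_score`.
* OOB permutation importance follows the classic per-tree recipe: per
  tree, misclassification error on its out-of-bag rows, re-computed after
  shuffling one feature over those rows; importance is the mean error
  increase over trees. Trees without OOB rows are skipped with a warning.
* Degenerate inputs error early with named causes: single-class labels,
  empty validation distributions, all-N sequences, all-missing
  conservation, empty FASTA/BED files (with line numbers for malformed
  lines).

## Problem sizes in tests and the acceptance script

The shipped checks run the full pipeline at 500 + 500 sequences of
200–1000 nt with `hash_dim` 8192 (encoder defaults R = 2, D = 4), tree
count 80, Top-101 selection; calibration consistency uses 2000 calibration
and 2000 fresh negatives on basic features; importance recovery uses 10
runs of 300 × 51 matrices; tuning consistency uses a 10…100 grid at
300 basic-feature rows. These sizes were chosen as the smallest at which
the statistical checks have comfortable margins.

## Known limitations

* The graph encoder is structure-free: it encodes the backbone path
  only, not secondary-structure base pairs.
* FASTA-mode inputs cannot use the `all` profile without id-keyed tracks;
  `sequence_only` is the documented FASTA path.
* Only single-interval BED entries are supported (no BED12 multi-exon
  entities).
* Exact tandem arrays miss degenerate (mismatch-containing) repeats that
  alignment-based finders would report.
* The fractile display rounds to whole percent; two inputs can share a
  displayed score while differing in mean fractile.
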