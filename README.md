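# circpot

Predicting circular RNA potential from primary sequence.

Circular RNAs (circRNAs) arise when a downstream splice donor backsplices
to an upstream acceptor, producing a covalently closed transcript. Most
annotated circRNAs come from RNA-seq pipelines that hunt for
junction-spanning reads and suffer from high false-positive rates.
`circpot` takes the complementary, sequence-first approach: given a
transcript (FASTA) or a genomic interval (BED6 plus a genome FASTA), it
scores how circRNA-like the sequence looks, using only features derivable
from the sequence and optional annotation tracks. It is aimed at
bioinformaticians who want to triage candidate circRNAs, post-filter
RNA-seq circRNA calls, or train their own classifier on labeled sequence
sets (e.g. circRNA vs protein-coding gene, circRNA vs lncRNA, or
stem-cell-expressed vs not).

## The method

Each sequence is encoded into a feature vector with up to four groups
(178 features in the full profile):

* **Basic (70):** length, GC content, the 64 trinucleotide frequencies,
  and the GT / AG / GTAG / AGGT motif frequencies (splice-site
  dinucleotides and their backsplice-order concatenations).
* **Graph (Top-101):** the sequence is a labeled path graph (one node per
  base); for every pair of rooted neighborhoods with radius r ≤ R at
  backbone distance d ≤ D, a canonical key is hashed into a
  fixed-dimension count vector. A random forest ranks the hashed features
  on a labeled set and the Top-K (default 101) are retained.
* **Conservation (2):** mean and population SD of a per-base conservation
  score (bedGraph track).
* **Other (5):** ALU overlap fraction, exact tandem-repeat coverage,
  longest-ORF length and propensity, and SNP density.

All features are min-max normalized to [0, 1] on the training data.

Training runs a stratified five-fold cross validation: each fold fits a
random forest (tree count tuned over 10…100 by CV AUC, or fixed) and keeps
its held-out fold's score distribution. A new sequence is scored by all
five forests; each score *s* is converted to a fractile
(#{v &lt; s} + ½·#{v = s}) / n within that fold's validation distribution,
and the five fractiles are averaged — rank aggregation across the
ensemble. A held-out negative set calibrates an FPR table:
FPR(t) = fraction of negatives with mean fractile ≥ t.

A synthetic-data module generates labeled datasets with controllable class
signal (GC shift, planted GTAG motifs, conservation shift, ALU density) on
a toy genome with matching bedGraph/BED/VCF tracks, so the whole pipeline
is testable without downloads.

## Worked example

```bash
circpot simulate --out data --seed 5 --n-pos 80 --n-neg 80 --max-len 600
circpot train --pos-fasta data/pos.fa --neg-fasta data/neg.fa \
              --n-trees auto --top-k 101 --hash-dim 8192 --seed 5 --out model
circpot predict --model model --bed data/transcripts.bed --genome data/genome.fa
circpot evaluate --model model --pos-fasta data/pos.fa --neg-fasta data/neg.fa
```

The training report (stderr) shows the tuned tree count, the pooled
out-of-fold AUC, and the top features by OOB permutation importance —
here the planted signals (GC shift, GTAG motif) are recovered:

```
{"cv_auc": 0.9982, "fold_aucs": [1.0, 1.0, 1.0, 1.0, 1.0], ...,
 "n_trees": 50, "top_features": [{"importance": 0.074463, "name": "gc_content"},
 {"importance": 0.024931, "name": "freq_GTAG"}, ...]}
```

Prediction output is a TSV, one row per input; the score is the mean
fractile as a percentage and `fpr` the calibrated false-positive rate at
that score:

```
id        position            custom_score  custom_fpr
pos_0001  chr1:0-468(+)       81%           0.0
pos_0002  chr1:493-1007(-)    82%           0.0
pos_0003  chr1:1032-1276(-)   91%           0.0
```

`evaluate` prints `{"model": "custom", "auc": 1.0, "n_pos": 80, "n_neg": 80}`
on the training FASTAs. A score of 81% means the input outscored 81% of
the validation distribution on average across the five fold models; the
FPR column says how often a negative sequence reaches that score.

The same machinery is available as sklearn-style estimators
(`SequenceFeaturizer`, `FeatureNormalizer`, `GraphFeatureSelector`,
`FractileForestClassifier`) for use in Python, plus functional wrappers
(`train_model`, `predict_table`, `score_to_fractile`, …).

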