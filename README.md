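# srnarank

Genomic-context characterization and probabilistic ranking of bacterial
small RNA (sRNA) candidates.

RNA-seq experiments routinely report hundreds of putative sRNAs per
bacterial genome, but validating each one by Northern blot is
impractical. `srnarank` helps microbiologists decide which candidates to
take to the bench: it represents each candidate by seven genomic-context
and structure features, trains probabilistic classifiers against
length- and strand-matched random genomic loci, and ranks candidates by
their probability of being bona fide sRNAs. Because the features capture
*where* an sRNA sits (promoter upstream, intrinsic terminator downstream,
intergenic location) rather than *what* its sequence is, the learned
models transfer across species despite the notoriously poor sequence
conservation of sRNAs.

## The feature vector

Each candidate `s` (a stranded interval on the genome) is mapped to

| # | feature | definition | range |
|---|------------------|--------------------------------------------------------------|------------------|
| 1 | `energy` | stability score of the predicted secondary structure | (−∞, 0] |
| 2 | `distPromoter` | signed distance from the 5′ start to the closest −10 box found from 150 nt upstream to the 3′ end | {−1000} ∪ [−(len−1), 150] |
| 3 | `distTerminator` | distance from the 3′ end to the closest same-strand Rho-independent terminator | [0, 1000] |
| 4 | `distLeftORF` | gap to the annotated ORF at lower coordinates (0 if overlapping) | (−∞, 0] |
| 5 | `sameStrandLeft` | 1 iff the candidate shares the left ORF's strand | {0, 1} |
| 6 | `distRightORF` | gap to the annotated ORF at higher coordinates (0 if overlapping) | [0, +∞) |
| 7 | `sameStrandRight`| 1 iff the candidate shares the right ORF's strand | {0, 1} |

The sentinels −1000 / 1000 encode "no site found in range". Promoter and
terminator sites and the structure score come either from external
predictor output (BPROM text reports, TransTermHP predictions, BED
files, precomputed energy TSVs) or from built-in fallbacks — a
position-weight-matrix scan for TATAAT-like boxes, a hairpin + U-tract
detector, and a weighted Nussinov fold — so the whole pipeline runs with
no third-party binaries.

Five classifier families are supported (`LR`, `MP`, `RF`, `AB`, `GB`;
logistic regression through gradient boosting), with defaults fixed at
the settings tuned by leave-one-out cross-validated AUC for this task —
notably a 400-tree, depth-20 random forest with 2 features per split,
whose probability output (the mean of per-tree class frequencies) is the
recommended ranking score. Model comparison tooling (AUPRC,
winner-gets-all ranks, Friedman test with Nemenyi/Quade/Conover
post-hocs, Benjamini–Hochberg FDR) and out-of-bag permutation importance
are in `srnarank.evaluation`.

## Worked example

Simulate a small genome with five planted sRNAs (each given an exact
TATAAT box 35 nt upstream and an intrinsic terminator 20 nt downstream),
characterize them, train a forest against 3:1 matched negatives, and
rank:

```sh
srnarank simulate --seed 1 --genome-length 20000 --n-orfs 14 --n-positives 5 --out fx
srnarank characterize --srnas fx/positives.bed --genome fx/genome.fa \
    --orfs fx/orfs.bed --out features.tsv
cat features.tsv
```

```
name    energy  distPromoter  distTerminator  distLeftORF  sameStrandLeft  distRightORF  sameStrandRight
srna000 -104.0  35            20              -704         0               77            0
srna001 -132.0  35            20              -118         0               45            1
srna002 -200.0  35            20              -67          0               95            0
srna003 -171.0  35            20              -85          1               47            0
srna004 -60.0   35            20              -75          1               127           1
```

Every planted candidate recovers exactly the planted geometry: a −10 box
35 nt upstream, a terminator 20 nt downstream, and strictly intergenic
ORF gaps (negative left, positive right). After

```sh
srnarank sample-negatives --positives fx/positives.bed --genome fx/genome.fa \
    --pool-ratio 3 --seed 1 --out negatives.bed
# label the two characterize outputs 1/0 and concatenate into training.tsv, then:
srnarank train --classifier rf --data training.tsv --seed 1 --out model.bin
srnarank rank --model model.bin --features features.tsv --out ranked.tsv
```

the ranking assigns each planted sRNA a high bona fide probability:

```
name     probability  rank
srna000  0.9425       1
srna001  0.93         2
srna003  0.8975       3
srna002  0.885        4
srna004  0.835        5
```

In a real analysis, `--srnas` is your BED of RNA-seq-derived candidates,
`--genome`/`--orfs` come from the reference assembly, and
`--bprom`/`--transterm`/`--energies` feed in external predictor output
instead of the fallbacks.

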