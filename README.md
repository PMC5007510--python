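# pseudorank

Detect remote protein homologs by fusing several homology-search
predictors. The package provides:

- **Pseudo protein sequences** — build a 20×L per-position amino-acid
  frequency profile for a query (from a multiple sequence alignment or a
  PSI-BLAST ASCII PSSM) and emit the per-column argmax consensus as a
  plain FASTA sequence that any sequence-input search tool can consume.
- **Rank aggregation** — per-query min–max normalization of each
  predictor's scores to [0, 1], then a weighted convex combination over
  the union of candidate targets; absent targets contribute 0.
- **Evaluation** — jackknife (leave-one-out) ranked retrieval on a
  family/superfamily-labelled benchmark, scored with ROC1/ROC50
  (area under the TP-vs-FP step curve truncated at the n-th false
  positive, normalized to [0, 1]), plus exceedance curves and pairwise
  win/tie/loss comparisons.
- **Weight search** — exhaustive grid search over the weight simplex
  maximizing mean ROC1 (or ROC50).
- **Adapters** — parsers for BLAST `-outfmt 6`, HMMER3 `--tblout`,
  HHblits/HHsearch `.hhr`, and a generic 3-column TSV
  (`query_id  target_id  score`), all normalized to higher-is-better
  scores; optional shell-out to user-installed binaries.
- **Synthetic benchmarks** — seeded generators for labelled sequence
  hierarchies, MSAs with per-column conservation, and predictor score
  lists with known signal strength, so the whole pipeline is testable
  offline.

## CLI

```sh
# synthetic fixtures: FASTA + labels + per-predictor score TSVs
pseudorank simulate --seed 1 --outdir fixtures/

# MSA or PSSM -> pseudo protein sequence FASTA
pseudorank pseudo --msa aln.fasta -o pseudo.fasta
pseudorank pseudo --pssm query.pssm -o pseudo.fasta

# fuse ranking lists (weights match -l order, must sum to 1)
pseudorank aggregate -l fixtures/p1.tsv -l fixtures/p2.tsv -l fixtures/p3.tsv \
    -w 0.01,0.29,0.7 -o combined.tsv

# jackknife ROC1/ROC50 against the labelled benchmark
pseudorank evaluate -r combined.tsv -b fixtures/labels.tsv -o summary.tsv
pseudorank curve -s summary.tsv --metric roc50 -o curve.tsv

# exhaustive simplex grid search for the weights
pseudorank optimize-weights -l fixtures/p1.tsv -l fixtures/p2.tsv \
    -l fixtures/p3.tsv -b fixtures/labels.tsv --step 0.1 -o weights.json
```

Ranking TSVs are `query_id<TAB>target_id<TAB>score` (one predictor per
file, higher scores better); benchmark labels are
`seq_id<TAB>family_id<TAB>superfamily_id`.

## Layout

```
src/pseudorank/
  profiles.py      frequency profiles, pseudo sequences, PSSM/MSA parsing
  aggregation.py   min-max normalization, weighted score fusion, TSV I/O
  evaluation.py    benchmark model, ROC_n, jackknife, curves, comparisons
  weights.py       simplex enumeration and grid search
  adapters.py      predictor output parsers + optional invocation
  simulate.py      seeded synthetic benchmarks / MSAs / score lists
  cli.py           click command group (`pseudorank`)
```
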