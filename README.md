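# mnm

Subpopulation-aware analysis of single-cell whole-genome copy-number data:

1. **IO / rebinning** — read BED-like or matrix-layout copy-number tables and
   rearrange arbitrary input bins into fixed genomic windows (median of
   inputs overlapping a window by ≥ 50% of their length).
2. **Barcode QC** — separate valid from invalid sequencing barcodes by read
   count: hard 30,000-read floor, two-component log-normal EM fit, and a
   cutoff at the density crossing (or at a Type-I-error quantile).
3. **Imputation** — distance-weighted 5-nearest-neighbour imputation of
   missing copy numbers, with median/random baselines and
   accuracy / similarity / invariance evaluation metrics.
4. **Replication-state classifier** — a 64/32/16/1 sigmoid feed-forward
   network (NumPy implementation, Adam + binary cross-entropy, early stopping
   with patience 15) labelling each cell Replicating (S) or Non-replicating,
   with ±1-copy data augmentation and predict-time linear interpolation of
   absent regions.
5. **Subpopulation discovery** — 2-D UMAP + DBSCAN with a coordinate-range
   epsilon rule (clamped to [1.25, 2]), six-seed cluster-count voting,
   98.5%-identity cluster merging, and matching of replicating cells to
   subpopulations by nearest-neighbour vote in a 10-D UMAP embedding; five
   constant-ploidy calibration cells (1N–5N) anchor both embeddings.
6. **RT utilities** — binarise S-phase profiles against a G1 baseline,
   pseudo-bulk replication-timing profiles, Spearman correlation atlas with
   Ward-linkage ordering, and a label-permutation test for trajectory
   coordinates.
7. **Synthetic cohorts** — clonal populations with integer karyotypes, ±1
   noise, prefix-replicating S-phase cells, random masking, and log-normal
   barcode counts, so that every stage is testable offline.

## CLI

Every stage is a subcommand of `mnm`; the pipeline is a thin sequencer over
them.

```sh
mnm simulate --config sim.yaml --out-prefix cohort     # synthetic cohort
mnm rebin --input calls.bed --layout bed --binsize 100000 \
          --chrom-sizes sizes.tsv --output rebinned.tsv
mnm barcodes --counts counts.tsv --min-reads 30000 --mode posterior --out bc
mnm impute --input rebinned.tsv --layout matrix --k 5 --out imputed.tsv
mnm impute-bench --input cohort.bed --fractions 0.05:0.55:0.05 --seed 1 --out bench.tsv
mnm train --input cohort.bed --labels labels.tsv --seed 1 --out model.mnm
mnm classify --input sample.bed --model model.mnm --out phases.tsv
mnm subpop --input sample.bed --phases phases.tsv --seed 18671107 --out-dir run/
mnm rt --binary binary.tsv --groups groups.tsv --out-dir rt/
mnm trajtest --coords coords.tsv --n-perm 1000 --seed 1
mnm run --config config.yaml                           # end-to-end
```

`mnm run` consumes a YAML `RunConfig` (input path/layout, model path, bin
size, master seed — default 18671107 — and all stage thresholds) and writes
phase calls, subpopulation assignments, embeddings, per-subpopulation median
profiles, optional RT outputs, and a JSON manifest with per-stage counts.

## Layout

```
src/mnm/
  core.py        bin index + copy-number matrix containers
  io.py          BED/matrix readers & writers, rebinning
  synthetic.py   synthetic cohort generators
  cohorts.py     standard validation cohorts (used by acceptance)
  barcodes.py    log-normal mixture EM barcode validation
  impute.py      weighted KNN imputation + metrics + baselines
  classifier.py  replication-state MLP (train/predict/augment)
  subpop.py      UMAP + DBSCAN subpopulation discovery & S matching
  rt.py          binarisation, pseudo-bulk RT, correlations, permutation test
  pipeline.py    end-to-end runner + manifest
  cli.py         click CLI
```
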