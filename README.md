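# barcodekit

Analysis toolkit for aligned DNA-barcode libraries (COI-style, 658 bp by
convention but any equal-length alignment works):

- **seqio** — read/validate aligned FASTA + metadata TSV, collapse exact
  haplotypes, translation-based numt screen (invertebrate mitochondrial code,
  library-level reading-frame auto-detection).
- **distances** — Kimura 2-parameter pairwise distances with pairwise
  deletion, intraspecific (within/between population) vs interspecific
  partitioning, barcode gap/overlap analysis, percentile thresholds.
- **identify** — leave-one-out best match (BM), best close match (BCM) and
  all species barcodes (ASB) protocols; TP/FP/TN/FN confusion sweep over
  descending thresholds; OLS-based ad hoc threshold solving a target
  relative identification error.
- **bpnet** — single-hidden-layer back-propagation classifier (one-hot
  column encoding, SGD + momentum, lr 0.2 / momentum 0.5 / MSE goal 1e-5
  defaults) with a stratified ~1:1 reference/query split.
- **network** — minimum spanning networks over haplotypes with co-minimal
  tie-edge retention and an optional mutational-step connection limit;
  minimum steps between groups; shared-haplotype reports.
- **njtree** — neighbor joining on the K2P matrix, column-resampling
  bootstrap support, unrooted monophyly assessment per label.
- **synthetic** — seeded K80-process simulator generating libraries with
  known ground truth (within/between-population and interspecific distance
  targets, cross-population haplotype sharing, "oversplit" scenarios where
  several nominal labels ride on one true species).
- **cli** — subcommands per stage plus `run` for the full report bundle.

## CLI

```sh
# generate a synthetic library with ground truth
barcodekit simulate --seed 1 --out demo

# individual stages
barcodekit distances demo.fasta demo_metadata.tsv --out dm.tsv
barcodekit gap demo.fasta demo_metadata.tsv --out gap.json
barcodekit identify demo.fasta demo_metadata.tsv --protocol bcm --threshold auto --out id.tsv
barcodekit sweep demo.fasta demo_metadata.tsv --points 30 --out sweep.tsv
barcodekit adhoc demo.fasta demo_metadata.tsv --target 0.05
barcodekit bpnet demo.fasta demo_metadata.tsv --seed 1 --out bp.tsv
barcodekit network demo.fasta demo_metadata.tsv --out-prefix net
barcodekit njtree demo.fasta demo_metadata.tsv --replicates 1000 --seed 1 --out tree.nwk

# everything at once (distance matrix, gap report, BM/BCM/ASB summaries,
# sweep + ad hoc fit, network exports, NJ tree + monophyly, provenance JSON)
barcodekit run --sim-config sim.json --outdir out/
barcodekit run --fasta lib.fasta --metadata lib.tsv --bpnet --outdir out/
```

Input metadata is a 4-column TSV with header
`seq_id	species	population	locality`.

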