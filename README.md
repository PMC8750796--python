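# srnaland

Small-RNA analysis toolkit for plant sRNA-seq: locus calling and
classification, tRNA-derived small RNA (tsRNA) identification, permutation
overlap testing against genomic features, siren detection and
methylation/expression-integrated siRNA24 target prediction — plus a
synthetic-data generator with a planted ground-truth manifest so the whole
chain is testable without any external downloads.

## What it does

- **core_io** — shared coordinate model (0-based, half-open) and readers /
  writers for FASTA, GFF3, BED6, a tabular alignment dialect, sample tables
  and per-cytosine methylation calls.
- **locus_profiler** — read clustering (75-nt merge gap, 0.5 RPM coverage
  floor), the 80% Dicer-length rule (`siRNA20`–`siRNA24` vs `OtherRNA`),
  FPKM quantification, expressed / novel / tissue-specific locus filters and
  5′-nucleotide profiling.
- **tsrna_pipeline** — dual tRNA reference (mature + CCA, and flank-extended
  primary), exact full-length read matching, positional classification into
  tRF-5 / tRF-3 / tRF-1 / 5tiR / 3tiR, positional profiles,
  reference-normalized abundance with log2 fold changes, Kendall tau-b.
- **region_association** — permutation overlap test (region counts, uniform
  re-placement nulls, z-scores, plus-one empirical p, moment-based
  normality gate).
- **seed_analysis** — gene expression binning, strand-aware 1-kb gene
  flanks, methylation fractions, siren calling at FPKM > 10^2.25, phasing
  register analysis, 2×2 chi-squared, and integrative siRNA24 target
  prediction; `run_seed_pipeline` orchestrates the chain end to end.
- **synthetic_data** — deterministic toy genome, annotations, multi-tissue
  replicate read sets, methylation and expression tables, with planted
  tsRNAs of every class, planted endosperm sirens, TE-enriched 24-nt
  clusters and silenced methylated target genes, all recorded in a
  ground-truth manifest.

## CLI

```sh
srnaland simulate --seed 1 --out data/            # synthetic dataset + manifest
srnaland loci     --in data/ --out out/loci/      # call/classify/quantify loci
srnaland tsrna    --in data/ --out out/ts/        # tRNA reference + tsRNA hits
srnaland assoc    --in data/ --out out/assoc/     # permutation tests vs TEs
srnaland siren    --in data/ --out out/siren/     # siren calling (endosperm)
srnaland run-all  --in data/ --out out/all/       # full seed pipeline
```

All outputs are plain TSV/GFF3/FASTA/JSON; reruns with the same inputs are
byte-identical.

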