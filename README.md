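# ampcnv

Copy-number variant (CNV) calling from multiplex amplicon sequencing read
counts. Starting from per-amplicon raw read counts (no BAM/FASTQ handling),
`ampcnv` normalizes counts to a per-amplicon value centered on 1 (0.5 at a
heterozygous deletion, 1.5 at a duplication), flags amplicons by one-tailed
z-score thresholds, segments runs of flagged amplicons into DEL/DUP calls
with a single-gap merge heuristic, and exports calls as TSV and VCF 4.2.
It also ships a synthetic run generator and a tumor-cell-fraction dilution
model, so the entire pipeline is testable without external data.

## What's inside

| module | purpose |
| --- | --- |
| `ampcnv.panel_io` | amplicon designs (BED / TSV), coverage tables, run matrices |
| `ampcnv.normalize` | low-coverage filtering, primer-pool shares, stable-reference scaling, cross-sample median ratio (with control-sample mode) |
| `ampcnv.detect` | z-score classification, run-length segmentation, gap merging, two-stage ratio refinement |
| `ampcnv.charts` | per-chromosome CUSUM and Loess diagnostic tracks (numeric, no GUI) |
| `ampcnv.simulate` | synthetic designs/runs, CNV injection via the carrier-fraction dilution formula, dilution sweeps |
| `ampcnv.report` | VCF 4.2 export (symbolic `<DEL>`/`<DUP>` alleles), calls and per-amplicon TSV tables |
| `ampcnv.benchmarks` | panel-scale synthetic experiments used by the acceptance suite |

Detection pipeline in one paragraph: raw cells below `--min-reads` (default
20) are masked; counts become within-pool shares per sample; each sample is
scaled by its mean over the most stable (lowest-CV) amplicons; each cell is
divided by the per-amplicon median across samples (or across the declared
controls); per sample, z = (NRC − mean) / population SD, with one-tailed
significance at alpha 0.01; runs of ≥ 3 same-direction flagged amplicons on
one chromosome become calls; two calls split by exactly one amplicon that is
significant at 0.05 are merged (optionally also by a maximum genomic
distance). A second pass recomputes the median ratio with each sample's
first-pass CNV amplicons removed from the denominators and repeats
detection — this "two-stage ratio" removes the bias seen when many samples
share an event.

## CLI

```sh
# generate a synthetic run with one injected heterozygous deletion
ampcnv simulate --n-samples 8 --n-genes 40 --seed 1 \
    --inject S3:GENE007:1:1.0 --out-prefix scratch/demo

# call CNVs (calls TSV, per-amplicon TSV, NRC TSV, one VCF per sample)
ampcnv call --design scratch/demo.design.tsv --matrix scratch/demo.counts.tsv \
    --out-prefix scratch/demo_results
# with controls: add --controls S5,S6,S7 ; tune --alpha/--min-amplicons/
# --min-reads/--merge-distance, or disable refinement with --no-two-stage

# diagnostic tracks (NRC, Loess fit, CUSUM S+/S-) per sample
ampcnv tracks --design scratch/demo.design.tsv --matrix scratch/demo.counts.tsv \
    --out-dir scratch/demo_tracks

# NRC matrix only, or re-export a calls TSV to VCF
ampcnv normalize --design ... --matrix ... --out nrc.tsv
ampcnv export --design ... --calls demo_results.calls.tsv --sample S3 --out s3.vcf
```

Coverage input is either a combined matrix TSV (first column `amplicon_id`,
one column per sample, empty cell = missing) or `--coverage-dir` with one
two-column TSV (`amplicon_id`, `total_reads`) per sample. Designs are
tab-separated with header `chrom/start/end/amplicon[/gene/pool]` (1-based
inclusive) or BED via `--design-dialect bed0`.

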