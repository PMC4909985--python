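# mosaicx

Detection, phasing and validation of large (>2 Mb) mosaic structural events
on the female X chromosome from SNP-array data, plus the cohort statistics
that go with such a scan. The package covers the full analysis chain:

- **probe_model** — probe maps, per-sample BAF/LRR/genotype vectors,
  informative-probe selection, mirrored BAF, batch LRR baseline adjustment.
- **segmentation** — circular binary segmentation of mirrored BAF with
  permutation significance, and size/deviation filtering of candidates.
- **event_caller** — Gaussian-mixture BAF-band typing, copy-state
  assignment from adjusted LRR, mosaic cell-fraction estimation,
  chromosomal location classification, constitutional-aneuploidy screening.
- **methylation_phasing** — selection of sex-differentially methylated X
  promoter probes, expected-beta modelling, z-score phasing of events to
  the inactive (Xi) or active (Xa) homolog, and the Xi-preference test.
- **qpcr_validation** — standard-curve quantification of X copy ratio
  against an autosomal reference, 3-SD gain/loss calling, concordance.
- **cohort_stats** — Wilson intervals, exact binomial tests, odds ratios,
  logistic regression (IRLS), length-adjusted event rates, event summaries.
- **synthetic_data** — deterministic generators for SNP-array, methylation
  and qPCR data with known ground truth, so every stage is testable
  offline.
- **pipeline_cli** — the `mosaicx` command-line interface.

Coordinates are 0-based half-open in memory and in BED-like outputs;
tab-separated interchange files use 1-based inclusive positions.

## CLI

```sh
# generate a synthetic cohort (probe TSV, cohort TSV, ground truth)
mosaicx --seed 7 simulate --out-dir runs/demo --n-women 200 \
    --with-methylation --with-qpcr

# scan for mosaic events
mosaicx --seed 7 detect --probes runs/demo/probes.tsv \
    --out runs/demo/events.bed

# phase events to Xi/Xa from promoter methylation
mosaicx phase --events runs/demo/events.bed \
    --betas-women runs/demo/betas_women.tsv \
    --betas-men runs/demo/betas_men.tsv \
    --betas-carriers runs/demo/betas_carriers.tsv \
    --annotation runs/demo/meth_annotation.tsv \
    --out-dir runs/demo/phase

# qPCR copy-ratio quantification and calling
mosaicx qpcr --plate runs/demo/plate.csv --out-dir runs/demo/qpcr

# cohort summary tables
mosaicx stats --events runs/demo/events.bed \
    --cohort runs/demo/cohort.tsv --out-dir runs/demo/stats
```

All stage parameters can come from a YAML config (`--config FILE`) with
flag overrides; unknown config keys are rejected. Every run writes a
provenance header (version, config hash, seed) to its outputs.

## Notes

- The length-adjusted event rate uses the documented definition
  `events / (individuals x territory_Mb / 1e4)`; published rate values
  based on an unspecified adjustment are not reproducible from it.
- Male X mosaicism calling is out of scope.
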