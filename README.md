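# telodisjoin

Quantitative pipeline for studying condensin enrichment and sister-telomere
disjunction at chromosome ends, built to run end-to-end on synthetic
two-species genomes with planted ground truth:

- **Spike-in calibrated ChIP** (`telodisjoin.chip`): fragment-overlap
  coverage tracks, a calibration factor that equalizes IP and Total on the
  spike-in species, per-base calibrated IP/Total ratio tracks with
  quantification masks, qPCR-style control-locus normalization, and
  metagene profiles (scaled gene body plus fixed flanks, TSS always
  leftmost).
- **Hi-C telomere-pair aggregation** (`telodisjoin.hic`): square-root
  vanilla-coverage (VC_SQRT) normalization, observed/expected, median
  distance-decay curves, log2 differential maps, and aggregation of
  end-region submatrices over all telomere pairs (150 kb regions at 5 kb,
  21×21 sliding windows, rank quantization) with Mann-Whitney condition
  comparisons per pair class (intra / inter / centromere control).
- **Mitotic foci analysis** (`telodisjoin.foci`): single-linkage focus
  merging at a resolution-scale radius, stage classification from SPB-SPB
  distance (≤4 µm metaphase, ≤5 µm anaphase, >5 µm late anaphase), and
  disjunction scoring (>2C separated, ≥4C fully disjoined, ≤2C
  non-disjoined for C chromosomes).
- **Synthetic data** (`telodisjoin.simulate`): two-species ChIP fragment
  sets with configurable mixing ratio and planted fold enrichments;
  Rabl-like Hi-C matrices (power-law decay, telomere/centromere clustering
  gains, multinomial/Poisson/noise-free sampling); mitotic cells as 3D
  point sets across interphase/metaphase/anaphase states.
- **Statistics** (`telodisjoin.stats`): self-contained Mann-Whitney-Wilcoxon
  test with an exact enumerated null (ties handled exactly) and a
  tie-corrected normal approximation; replicate summaries; optional Holm
  adjustment.
- **Orchestration** (`telodisjoin.pipeline`): YAML scenario configs, hashed
  per-stage child seeds, full deterministic runs with checksummed
  manifests, and wild-type-like vs condensin-mutant-like presets.

## CLI

```bash
telodisjoin genome build --out-dir out/genome
telodisjoin sim hic --seed 1 --out out/wt.tsv
telodisjoin hic normalize --matrix out/wt.tsv --out out/wt.vc.tsv
telodisjoin hic oe --matrix out/wt.tsv --out out/wt.oe.tsv
telodisjoin sim cells --seed 1 --out out/cells.tsv
telodisjoin foci profile --cells out/cells.tsv --out-prefix out/foci
telodisjoin run --preset wt_vs_cut14 --seed 1 --out-dir out/scenario
```

`telodisjoin run` executes a full scenario (genome → simulators → ChIP
calibration → Hi-C aggregation → foci scoring → condition comparisons) and
writes a `manifest.json` whose checksums are byte-identical across reruns
with the same config and master seed. See
`telodisjoin.pipeline.ScenarioConfig` for the YAML schema
(`ScenarioConfig.to_yaml` writes a template).

## Conventions

- All genomic coordinates are 0-based, half-open (BED convention);
  1-based boundaries are converted at the input edge.
- Telomere end regions are oriented so index/bin 0 is always the
  repeat-proximal (outermost) position, for left and right ends alike.
- Masked positions are carried as missing values (NaN), never zeros, and
  are omitted from bedGraph output.
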