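# loopcgh

CNV discovery from two-color array-CGH experiments laid out as a dye-swap
loop design. The package covers the full analysis chain:

1. **synthetic** — simulation of complete experiments: genome model with
   assembly gaps, probe tiling (301 bp median spacing by default), animal
   panel, planted gains/losses, ring loop design, and two-channel
   intensities with dye bias, spatial artifacts and Gaussian noise.
2. **preprocess** — per-array spatial correction (loess-style local
   regression over array grid coordinates) and q-spline quantile
   normalization of the two channels against their geometric-mean
   pseudo-reference.
3. **segmentation** — exact penalized least-squares segmentation of each
   log2-ratio profile by dynamic programming, plus the candidate filter
   (|mean log2 ratio| ≥ 0.4 and ≥ 5 consecutive probes).
4. **calling** — dye-swap concordance (an aberration must appear on both
   mates with opposite raw sign) and loop attribution (two hybridization
   pairs sharing exactly one animal assign the CNV, its direction giving
   gain vs loss).
5. **cnvr** — cross-animal merging of overlapping same-direction calls
   into copy-number-variable regions and catalogue summary statistics
   (counts, mean/median sizes, genome percents, size histogram).
6. **qc_fpr** — false-positive rates from sex-mismatched hybridizations
   (wrong-direction chrX footprint) and self-self hybridizations, at
   single-array and dye-swap-concordant stringency.
7. **enrichment** — permutation tests of CNVR overlap with feature BEDs
   (length-preserving uniform re-placement per chromosome, gap-aware) and
   GC-content comparison against the genome.
8. **stats** — exact binomial test (minimum-likelihood two-sided),
   Wilcoxon rank-sum with exact small-sample null, and dN/dS comparison by
   CNV class.

## Command line

```sh
# simulate a full experiment to TSV/BED files
loopcgh simulate --outdir sim --n-animals 8 --noise-sd 0.2 --seed 11

# run the whole calling pipeline on it
loopcgh run --outdir out --design sim/design.tsv --genome-length 2000000 \
    --tables sim/A01f.probes.tsv --tables sim/A01r.probes.tsv ...

# or simulate + call in one go
loopcgh run --outdir out --simulate --n-animals 8 --seed 11

# individual stages
loopcgh preprocess sim/A01f.probes.tsv --out norm.tsv --span 0.3
loopcgh segment norm.tsv --out segments.tsv --ratio-threshold 0.4 --min-probes 5
loopcgh merge calls.bed --out cnvrs.bed
loopcgh summarize calls.bed --genome-length 3247516410 --out summary.json
loopcgh fpr --mode sex-mismatch --aberrant-bp 25694212 \
    --chrx-length 88516663 --n-arrays 8
loopcgh enrich cnvrs.bed features.bed --chrom-sizes genome.sizes --n-perm 10000
loopcgh stats --test binomial --k 202 --n 304
```

All genomic files are BED-dialect 0-based half-open; probe tables may
declare 1-based closed input via `--coords 1-closed`. Pipeline runs write a
provenance manifest (resolved config, seeds, stage row counts) next to
their outputs and are byte-reproducible for a fixed seed.

## Layout

```
src/loopcgh/      synthetic, preprocess, segmentation, calling, cnvr,
                  qc_fpr, enrichment, stats, io, pipeline, cli
tests/            unit + property tests per module; test_acceptance.py
                  holds the acceptance criteria
scripts/          acceptance.py (report generator)
```
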