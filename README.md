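# regulomics

A toolkit for analysing chromatin accessibility and transcription-factor
occupancy dynamics across a treatment time course. It implements, as a
tested and reusable pipeline:

- **Interval algebra** (`regulomics.core`, `regulomics.io`): 0-based
  half-open genomic intervals, region sets, merging, overlap flags,
  5'-position read counting, and plain-text I/O (BED3/BED6+summit,
  chrom.sizes, refFlat-like gene TSVs, count-matrix TSVs, FASTA).
- **Differential open chromatin** (`regulomics.faire`): per-region,
  per-time-point scores — |mean of the time point's replicates − mean of
  all other samples| / (sum of the two groups' sample SDs) on
  library-normalized counts — calibrated against an empirical null built
  by permuting sample-to-time-point labels.
- **Differential TF binding** (`regulomics.chipdiff`): treated subpeaks
  are called differential when they do not overlap any control subpeak
  (≥1 bp) and their pseudocount-smoothed RPM fold change exceeds
  mean + 1 SD over all treated subpeaks.
- **Motif models** (`regulomics.motif`): PWMs with log2-odds "motif
  quality scores" in bits, exact score p-values by dynamic programming
  over a score grid, genome scanning on both strands, and
  occupancy-vs-score curves stratified by open-chromatin membership.
- **Annotation** (`regulomics.annotate`): strand-aware nearest-TSS
  distances, single-class genomic feature assignment with a fixed
  precedence, Gaussian-smoothed TSS-distance densities, one-sided
  binomial feature enrichment, and basal-plus-extension regulatory
  domains (5 kb upstream / 1 kb downstream basal, 1 Mb cap).
- **Co-occupancy** (`regulomics.cooccupancy`): directional overlap
  fractions (optionally restricted to open chromatin), input-normalized
  signal correlation matrices, and deterministic average-linkage
  clustering on 1 − r.
- **Expression analysis** (`regulomics.expression`): Welch-test
  differential calls (p < 1e-4 AND |log2fc| > 0.5), knockdown-dependence
  classification (dependent / independent / ambiguous), and ranked
  peak-density profiles with a 1,000-gene rolling mean.
- **Synthetic data** (`regulomics.simulate`): seeded generators for all
  of the above with known ground truth (negative-binomial counts with
  planted amplitude shifts, logistic motif-binding model with an
  open-chromatin multiplier, 2×2 expression design with planted
  dependent/independent genes).

## Command line

One subcommand per stage plus `run-all`:

```sh
regulomics run-all --config config.yaml --outdir out
# or stage by stage:
regulomics simulate   --seed 1 --outdir out
regulomics faire-diff --seed 1 --outdir out
regulomics chip-diff  --seed 1 --outdir out
...
```

A minimal `config.yaml`:

```yaml
seed: 1
simulate:
  chrom_lengths: {chrS: 2000000}
  n_faire_sites: 500
faire_diff:
  n_permutations: 50
  alpha: 0.05
```

Every stage writes its outputs plus a manifest entry
(`out/manifest/<stage>.json` with input hashes, parameters, and the
seed); reruns with identical inputs and seed are byte-identical.
`run-all` finishes with `out/summary.txt`, comparing calls against the
generator's ground truth.

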