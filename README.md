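# tdmr

Discovery of tissue-dependent differentially methylated regions (T-DMRs)
from methyl-sensitive restriction tiling-array data, built around a
synthetic data generator with planted ground truth so every stage is
testable offline.

The pipeline mirrors a three-tissue experimental design: genomic DNA is
digested at unmethylated ACGT restriction sites, the resulting fragments
are amplified and hybridized to a 25-mer tiling array, and relative
hypomethylation appears as elevated probe signal. The package implements:

- **`tdmr.synthetic`** — simulated chromosome, genes (both strands), ACGT
  sites, tiling probes with sequence-dependent affinity baselines, planted
  per-tissue hypomethylation inside TSS windows, matched COBRA
  quantifications, an expression matrix linked to downstream
  hypomethylation, and TF target lists with planted fold enrichment.
- **`tdmr.mat`** — probe-affinity regression (positional nucleotide
  indicators + log2 copy number), robust standardization, and a directed
  windowed site score: `sqrt(n_a + n_b) * (trimmed_mean_a - trimmed_mean_b)`.
- **`tdmr.cobra`** — methylation level = cut / (cut + uncut); per-directed-
  comparison score thresholds calibrated as the minimum score among
  COBRA-confirmed candidates (candidates require score > 2).
- **`tdmr.calling`** — strand-aware site assignment to [-7 kb, +3 kb) TSS
  windows, pairwise hypo calls (score >= threshold), tissue-hypo
  classification (hypo versus every other tissue), per-gene summaries and
  positional density profiles.
- **`tdmr.enrichment`** — one-sided Fisher's exact tests: functional
  categories, TF target overlap (list- or binding-site-interval-based with
  a 10 kb-upstream / 1 kb-past-3'-end extended gene region),
  downstream-fraction comparisons, nuclear-mt composition ratios.
- **`tdmr.expression`** — per-gene log2 expression ratios and rank-sum
  shift tests of upstream/downstream hypo gene classes against all
  nuclear-mt genes.
- **`tdmr.io` / `tdmr.cli` / `tdmr.pipeline`** — plain-text schemas
  (TSV/BED), YAML config, and a subcommand CLI.

## CLI

```sh
# simulate a dataset with planted truth
tdmr simulate --outdir data --seed 17

# full pipeline: score -> calibrate -> call -> enrich -> express
tdmr run --indir data --outdir run1
tdmr report --rundir run1            # or --json for the manifest

# individual stages
tdmr score --probes data/probes.tsv --intensities data/intensities.tsv \
    --sites data/sites.bed --out scores.tsv
tdmr calibrate --scores scores.tsv --cobra data/cobra.tsv --out thresholds.tsv
tdmr call --scores scores.tsv --thresholds thresholds.tsv \
    --annotation data/annotation.tsv --sites data/sites.bed --outdir calls
tdmr enrich --summary calls/gene_summary.tsv --annotation data/annotation.tsv \
    --targets data/tf_targets.txt --tissue liver
tdmr express --expr data/expression.tsv --summary calls/gene_summary.tsv \
    --out expression_report.tsv
```

Exit code 2 signals a validation error. All randomness flows from a single
seed; reruns with the same seed and inputs are byte-identical.

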