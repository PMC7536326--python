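# germdrift

Within-class multivariate analysis of transgenerational germline-transcriptome
drift. Starting from a gene × sample integer count matrix collected over
several lineages and ordered generation states, the package:

1. normalizes counts with median-of-ratios size factors and log2(x+1)
   transforms them (`germdrift.preprocess`),
2. filters the gene universe by maximal log-expression and renders the
   max/SD diagnostic (`filter_expressed`, `expression_sd_summary`),
3. runs sample PCA, PCA on within-lineage expression differences, and
   within-class analysis (WCA: PCA after removing each lineage's mean
   profile) built from first principles with 1/n row weights
   (`germdrift.multivariate`),
4. turns first-component gene loadings ("WCA scores") into top-N
   downregulated/upregulated contributor lists and classifies per-gene
   trajectories (priming, amplification) (`germdrift.contributors`),
5. computes hypergeometric over/under-enrichment against gene sets (GMT) and
   chromosomes, fold enrichment, list overlaps, and X-vs-autosome score
   comparisons (`germdrift.enrichment`).

A negative-binomial simulator (`germdrift.simulate`) generates count matrices
with the same 3-lineage × 4-state structure and planted ground truth
(progressively deregulated genes, lineage-private effects, configurable
X-chromosome bias), so every downstream stage is testable without external
data. A surrogate moments-based NB Wald test (`de_count_vs_p0`) reproduces
"genes deregulated vs founder" counting; it is explicitly a stand-in for
full NB-GLM machinery and feeds nothing downstream.

## CLI

Each stage is a subcommand; results go to files, stdout carries logs.

```sh
germdrift simulate   --out-dir out --seed 1 --n-genes 8000
germdrift normalize  --counts out/counts.tsv --out-dir out
germdrift de         --counts out/counts.tsv --design out/design.tsv --out-dir out
germdrift wca        --log out/log_expression.tsv --design out/design.tsv \
                     --universe out/universe.txt --out-dir out
germdrift contributors --scores out/wca_scores.tsv --log out/log_expression.tsv \
                     --design out/design.tsv --out-dir out --n-down 250 --n-up 1000
germdrift enrich     --up out/contributors_up.txt --down out/contributors_down.txt \
                     --universe out/universe.txt --annotation out/annotation.tsv \
                     --gene-sets out/truth_sets.gmt --scores out/wca_scores.tsv \
                     --out-dir out
```

Or everything at once (simulating inputs when no paths are configured),
writing a `manifest.json` with per-output SHA-256 checksums:

```sh
germdrift run-all --out-dir out --seed 1          # default synthetic run
germdrift run-all --config config.yaml            # YAML PipelineConfig
```

Runs are deterministic: a fixed seed and config reproduce byte-identical
outputs (floats are serialized at 10 significant digits).

## File formats

Tab-separated UTF-8 throughout: counts/normalized/log matrices (genes ×
samples, first column `gene_id`), design (`sample_id`, `lineage`, `state`),
annotation (`gene_id`, `chromosome`; minimal GFF3 extraction supported), gene
sets as GMT, gene lists one id per line, configs as YAML, manifests as JSON.
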