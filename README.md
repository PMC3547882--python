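# linkmark

Genome-context protein–protein functional-linkage scoring and
pathway-stratified ROC/AUC benchmarking.

`linkmark` implements five classic functional-linkage scorers over a shared
pair universe, all on a 0–1 scale:

| Method | Signal |
|--------|--------|
| **GN** (Gene Neighbor) | minimum circular gene-rank distance of the two orthologs in any one reference genome, orientation-ignored, subtracted from one |
| **GC** (Gene Cluster)  | probability that the orthologs are encoded from the same co-directional gene cluster (intergenic gap ≤ 100 nt) |
| **PP** (Phylogenetic Profiling) | Pearson correlation of divergence-normalized ortholog bit-score profiles over a dereplicated reference-genome set |
| **GM** (genome-distance Mirrortree) | Pearson correlation of per-protein inter-species distance matrices after subtracting a rescaled shared-ortholog genome-distance matrix (speciation-bias correction) |
| **ES** (Expression Similarity) | Pearson correlation of expression profiles over the most-varying conditions |

A benchmarking layer builds global and per-category (two-level pathway
annotation) gold standards, sweeps score thresholds into confusion counts,
ROC curves and trapezoidal AUC, and emits a category × method AUC summary
table plus TP/FP-versus-threshold series.

Because the original genome/expression/pathway inputs are not deposited
anywhere, the package ships a first-class synthetic-data generator
(`linkmark.synthetic_data`) that emulates every input — reference genome
tables, an RBH-style ortholog map with bit scores, an expression compendium,
per-protein distance matrices with shared-ortholog genome counts, and a
two-level pathway annotation — with four independent signal knobs
(`co_inheritance`, `operon_prob`, `coexpression`, `coevolution`) so each
scorer's recovery can be attributed to its own channel.

## CLI

```bash
# simulate a synthetic world (all inputs as plain TSV)
linkmark simulate --config world.yaml --out-dir world/

# score a pair list with each method
linkmark score-gn --genomes world/genomes --orthologs world/orthologs.tsv \
    --genome-counts world/genome_counts.tsv --pairs world/pairs.tsv --out gn.tsv
linkmark score-gc ... --max-gap 100 ...
linkmark score-pp --orthologs ... --genome-counts ... --dereplicate 0.90 ...
linkmark score-gm --matrices world/matrices --genome-counts ... \
    --genome-pairs world/genome_shared.tsv --min-common 10 ...
linkmark score-es --expression world/expression.tsv --top-k 300 ...

# evaluate score tables against a pathway annotation
linkmark evaluate --scores gn.tsv --scores es.tsv \
    --annotations world/annotations.tsv --out-dir eval/

# or run the whole thing end to end (simulate -> score -> evaluate -> report)
linkmark run --config cfg.yaml --out-dir out/ --methods gn,gc,pp,gm,es
```

`cfg.yaml` holds a `world:` section (see `linkmark.synthetic_data.WorldConfig`
fields; `seed` is mandatory) and an optional `run:` section
(`max_gap`, `top_k_conditions`, `min_common_species`, `dereplicate_threshold`).
Identical configs produce byte-identical outputs; every emitted file carries
the config hash and seed in its header comments.

## Layout

```
src/linkmark/
  data_io.py                domain types + TSV readers/writers
  genome_context.py         GN + GC scorers, gene-cluster detection
  phylo_profiling.py        PP scorer, dereplication, profile normalization
  mirrortree_gm.py          GM scorer, genome-distance matrix, correction
  expression_similarity.py  ES scorer, condition selection
  pathway_benchmark.py      gold standards, confusion counts, ROC/AUC
  synthetic_data.py         synthetic world generator + export
  pipeline.py               simulate -> score -> evaluate orchestration
  cli.py                    click CLI (`linkmark`)
```
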