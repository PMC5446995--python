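# cellage

Cell-type enrichment analysis of age-associated gene rankings.

`cellage` tests whether genes enriched in specific transcriptomic cell types
(derived from single-cell expression by z-score thresholding) are
concentrated toward the up- or down-regulated end of a signed
age-association gene ranking. The enrichment statistic is the AUROC (the
probability that a set member outranks a non-member); significance comes
from an empirical null built by permuting the cell → cell-type assignment
and re-deriving the gene sets per shuffle, with an empirical min-p FDR
across cell types. A complementary scan dissects each cell-type set by
functional-annotation (GO-style) groups within the set's own sub-ranking.

The label-permutation null matters because threshold-derived sets score
away from 0.5 even for random labels whenever broadly expressed
("non-specific") genes shift together in the ranking — an effect analytic
rank tests mistake for signal. The package ships a synthetic-data module
that reproduces this phenomenon (and plants markers, directional set
shifts, and annotations) so the full pipeline is testable offline.

## Layout

| module | role |
| --- | --- |
| `cellage.synthetic` | synthetic expression / age tables / homology / annotations with planted structure |
| `cellage.profiles` | zero-gene filtering, log + z standardization, per-type profiles, enriched & non-specific set derivation |
| `cellage.orthology` | 1:1 mouse→human symbol mapping of sets and ranking backgrounds |
| `cellage.rankings` | signed up→down rankings from (gene, p, direction) tables; directional merge; Spearman comparison |
| `cellage.enrichment` | AUROC, Mann–Whitney p, label-permutation null, empirical p/q, fixed-set tests |
| `cellage.go_scan` | annotation-term AUROC scan within cell-type sub-rankings, joint BH FDR |
| `cellage.pipeline` / `cellage.cli` | YAML-configured end-to-end runs, reports, manifests |

## CLI

```sh
# generate a synthetic dataset with a planted up-regulated cell type
cellage simulate --n-types 16 --cells-per-type 3 --n-genes 4000 \
    --markers-per-type 100 --marker-effect 4 --inject-up T01 --set-shift 2 \
    --seed 1 -o data/

# stage by stage
cellage profiles --expression data/expression.tsv --labels data/labels.tsv -o prof/
cellage rank --table data/age_table.tsv -o ranking.tsv
cellage enrich --expression data/expression.tsv --labels data/labels.tsv \
    --ranking ranking.tsv -B 1000 --seed 1 -o enrichment.tsv
cellage goscan --sets prof/sets.gmt --ranking ranking.tsv \
    --annotations data/annotations.tsv -o goscan.tsv

# or everything from a config
cellage run -c run.yaml
```

A `run.yaml` holds exactly one of a `synthetic:` section (generator
parameters) or an `inputs:` section (paths to expression, labels, age
table(s), homology, annotations), plus `tau` (default 2), `B` (default
10000), `seed`, `size_bounds` (default `[10, 200]`) and `outdir`. Runs are
deterministic for a fixed seed and write enrichment/scan TSVs, ROC-style
curve tables, a report, and a JSON manifest of all parameters and
drop/skip counts. Exit codes: 0 success, 2 validation error, 1 runtime
error.

Input formats: dense TSV or Matrix Market (+ gene/cell sidecars) for
expression; TSV for labels, age tables and rankings; GMT for gene sets;
Homologene-dialect or two-column TSV for homology; TSV or GAF 2.x for
annotations. All outputs are plain text.

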