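# stratade

Gender-stratified differential expression analysis toolkit for small
two-gender case/control expression studies (e.g. microarray profiles of
laser-microdissected neuron pools), with a synthetic-study generator so
the full pipeline is testable without any external data.

The pipeline stages:

- **preprocessing** — per-gene ANOVA batch-effect removal (grand means
  preserved, idempotent) and PCA-based QC of class separation.
- **differential** — two-class unpaired SAM (moderated d statistic with
  CV-minimising fudge factor s0, permutation-pooled p-values, q-values
  from estimated FDR at each |d| threshold), per-gene multi-factor
  ANOVA, signed linear-ratio fold changes, and significance-gated
  contrast lists (q < 0.05 with p < 0.01 "stringent" / p < 0.05
  "relaxed").
- **list_comparison** — probe-to-gene collapsing by ratio-space
  averaging, merged genes x contrasts fold-change matrices (0 = absent),
  exact overlap partitions with per-list up/down counts at fold
  cut-offs, and cross-stringency gender-status classification
  (male-specific / female-specific / shared / stringency-dependent).
- **enrichment** — one-sided Fisher (upper-tail hypergeometric) gene-set
  over-representation across lists, GMT I/O, and anchor restriction
  (sets significant in both an anchor list and a target list).
- **gtan** — bipartite gene-term association networks over selected
  terms, multi-term gene extraction, GraphML export.
- **keygenes** — composite key-gene tables from four boolean evidence
  flags plus list membership, annotated with gender status.
- **qpcr** — 2^-dCt relative quantification with endogenous-control
  normalisation, replicate flagging, expression tiers, and z-score
  concordance against array data.
- **synthetic** — seeded generator for expression studies (default
  design: 3 female controls, 3 female PD, 6 male controls, 7 male PD),
  planted gender-specific/shared effects, batch structure, enriched
  gene sets and matched triplicate Ct tables, all with ground truth.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-table
worked examples (probe collapsing, key-gene status counts, overlap
percentages), an exact hypergeometric sweep, SAM null calibration and
power benchmarks, and an end-to-end synthetic run.

## CLI

```bash
stratade simulate --config config.json --out simdir --seed 7
stratade preprocess --expr expr.tsv --meta meta.tsv --out corrected.tsv
stratade de --expr corrected.tsv --meta meta.tsv --contrast mN_mPD \
    --stringency stringent --perms 1000 --seed 7 --out mPD.tsv
stratade lists --inputs mPD.tsv --inputs fPD.tsv --out listdir
stratade enrich --lists mPD.tsv --lists fPD.tsv --gmt sets.gmt \
    --anchor allN_allPD --out enrichment.tsv
stratade gtan --list mPD.tsv --gmt sets.gmt --terms t1,t2 --out net.graphml
stratade keygenes --stringent ms.tsv --relaxed mr.tsv \
    --evidence evidence.tsv --out keygenes.tsv
stratade qpcr --ct ct.tsv --reference GUSB --array expr.tsv --out rel.tsv
```

All formats are plain text: TSV expression/metadata/lists/matrices,
GCT 1.2, GMT gene sets, long-format Ct tables, GraphML networks.
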