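# cnvsurv

Genome-wide CNV-burden and per-CNV mortality analysis as a tested, reusable
pipeline: call copy-number variants from SNP-array intensity signals with a
five-state HMM, apply sample- and region-level QC rules, compute per-individual
CNV burden, associate burden and region carrier status with prospective
mortality under left truncation, and combine two cohorts by fixed-effect
meta-analysis. A synthetic-cohort generator with known ground truth stands in
for cohort data that are not publicly deposited.

## Modules

| module | what it does |
| --- | --- |
| `cnvsurv.synthetic_data` | marker maps (~2.1 kb median spacing), LRR/BAF signals with implanted CNVs, Gompertz proportional-hazards survival with left truncation and planted effects |
| `cnvsurv.hmm_caller` | PennCNV-style emissions (Gaussian LRR x Hardy-Weinberg BAF mixture), distance-modulated Viterbi decoding, call extraction with 3-SNP / 1 kb filters |
| `cnvsurv.qc` | per-sample LRR SD, call count and GC wave factor; exclusion at strict thresholds 0.30 / 100 / 0.05 |
| `cnvsurv.cnvr` | 50%-of-shorter overlap merging (transitive closure), centromere/telomere and <1% frequency exclusion, carrier matrix |
| `cnvsurv.burden` | per-sample CNV count, average and total length, with pre-scaled covariates (per 10 CNVs, per 10 kb, per 100 kb) |
| `cnvsurv.survival` | delayed-entry Cox partial likelihood (Efron ties, Newton-Raphson, cluster-robust sandwich variance), region-wise carrier tests |
| `cnvsurv.meta` | inverse-variance fixed-effect pooling of log hazard ratios; SE reconstruction from published confidence intervals |
| `cnvsurv.multitest` | Bonferroni thresholds and significance / suggestive / replication flags |
| `cnvsurv.pipeline` / `cnvsurv.cli` | end-to-end orchestration with manifests, config echo and byte-identical reruns |

The Cox engine is implemented in-house (not a wrapper); its estimates are
verified in the tests against brute-force grid search, `lifelines`, and, for
cluster-robust variance under delayed entry, R's `survival::coxph`.

## CLI

```sh
cnvsurv run-all --out run1 --seed 1          # full simulated discovery run
cnvsurv call --map run1/marker_map.tsv --signals run1/signals.tsv --out calls.tsv
cnvsurv qc --map ... --signals ... --calls ... --out qc.tsv
cnvsurv regions --calls calls.tsv --samples passing.txt --exclude centel.bed --out regions.tsv
cnvsurv burden --calls calls.tsv --samples passing.txt --out burden.tsv
cnvsurv assoc --phenotype pheno.tsv --matrix carriers.tsv --adjust sex --adjust entry_age --out assoc.tsv
cnvsurv meta --published per_study.tsv --out joint.tsv   # published-table mode
cnvsurv joint --discovery run1 --replication run2 --out joint_dir
```

All formats are plain TSV (1-based inclusive coordinates), plus PennCNV-style
`rawcnv` call lines and BED (0-based half-open, converted on read) for
exclusion intervals. Every run writes a `manifest.json` with row counts at
each filter and a verbatim `config.yaml` echo; reruns with the same seed are
byte-identical.

Published-table mode consumes a TSV of per-study rows
(`label, study, hr, ci_low, ci_high`) and regenerates joint-analysis columns
by reconstructing standard errors from the CI widths
(`se = (ln U - ln L) / (2 * 1.959964)`) and pooling with weights `1/se^2`.
The per-study association tables this package ships under
`cnvsurv.data` are accessible via `cnvsurv.published`.

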